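"""Cross-cohort replication of correlation directionality.

For each RBP, the discovery-significant (RBP, gene, trait) pairs are looked
up in a second cohort's correlation table and scored by the fraction whose
correlation keeps its sign.  Significance comes from permuting the
replication coefficients among the pairs (within the RBP) and comparing the
permuted fractions with the observed one:

    p = (1 + #{perm fraction >= observed}) / (1 + n_permutations)

The +1 smoothing keeps the p-value away from zero at finite permutation
counts.  Permutation p-values are BH-adjusted across RBPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlate import adjust_bh


class ReplicationError(ValueError):
    pass


@dataclass
class ReplicationResult:
    rbp: str
    n_pairs: int
    fraction: float
    p: float
    n_permutations: int
    seed: int | None = None
    p_adj: float = np.nan


def replication_fraction(discovery_rho, replication_rho) -> float:
    """Fraction of pairs with matching correlation sign.

    A replication coefficient of exactly zero counts as non-replicated.
    Returns NaN when there are no evaluable pairs.
    """
    d = np.asarray(discovery_rho, dtype=float)
    r = np.asarray(replication_rho, dtype=float)
    ok = np.isfinite(d) & np.isfinite(r)
    if not ok.any():
        return np.nan
    d, r = d[ok], r[ok]
    matched = (np.sign(d) == np.sign(r)) & (r != 0)
    return float(matched.mean())


def permutation_test(
    discovery_rho,
    replication_rho,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Observed replicated fraction and its permutation p-value."""
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    d = np.asarray(discovery_rho, dtype=float)
    r = np.asarray(replication_rho, dtype=float)
    ok = np.isfinite(d) & np.isfinite(r)
    d, r = d[ok], r[ok]
    n = len(d)
    if n == 0:
        raise ReplicationError("no evaluable pairs")
    if n < 10:
        warnings.warn(f"only {n} evaluable pairs; permutation p is unstable")
    observed = replication_fraction(d, r)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sign_d = np.sign(d)
    sign_r = np.sign(r)
    nonzero = (r != 0).astype(float)
    perm_mat = np.tile(np.arange(n), (n_perm, 1))
    perm_mat = rng.permuted(perm_mat, axis=1)
    matches = (sign_r[perm_mat] == sign_d[None, :]) & (nonzero[perm_mat] > 0)
    frac = matches.mean(axis=1)
    p = (1 + int(np.sum(frac >= observed - 1e-12))) / (1 + n_perm)
    return observed, float(p)


def replicate_rbps(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    trait: str | None = None,
) -> pd.DataFrame:
    """Per-RBP replication of discovery-significant correlations.

    Both inputs are long correlation tables (columns rbp, gene, trait, rho,
    significant for the discovery table).  Pairs are joined on (rbp, gene,
    trait); genes absent from the replication table are dropped.
    """
    disc = discovery[discovery["significant"]].copy()
    if trait is not None:
        disc = disc[disc["trait"] == trait]
    merged = disc.merge(
        replication[["rbp", "gene", "trait", "rho"]],
        on=["rbp", "gene", "trait"],
        suffixes=("_disc", "_repl"),
    )
    rows = []
    rng = np.random.default_rng(seed)
    for rbp, grp in merged.groupby("rbp", sort=True):
        obs, p = permutation_test(
            grp["rho_disc"].to_numpy(), grp["rho_repl"].to_numpy(),
            n_perm=n_perm, seed=rng,
        )
        rows.append({
            "rbp": rbp, "n_pairs": len(grp), "fraction": obs, "p": p,
            "n_permutations": n_perm,
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = adjust_bh(out["p"].to_numpy())
    return out
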