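"""Empirical target-set enrichment test, Glass' Delta and RBP classification.

The question "does this RBP's abundance predict its targets' trait more
often than chance" is answered empirically: draw many random gene sets of
the same size from the expressed universe, count BH-significant correlations
in each exactly as for the real target set, and compare.

    empirical p = #{null count >= observed} / n_sets   (floored at 1/n_sets)
    Glass' Delta = (observed - mean(null)) / sd(null)  (sample sd)

Empirical p-values are BH-adjusted across RBPs per trait; an RBP is an
mRNA-RBP and/or a TE-RBP when the adjusted p is <= alpha, and
"multifunctional" when both.  The null counts reuse the per-gene correlation
p-values against the RBP, so the null and the observation share the exact
same testing convention (BH within each set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .correlate import adjust_bh


class EnrichmentError(ValueError):
    pass


@dataclass
class NullDistribution:
    counts: np.ndarray  # significant-count per sampled set
    set_size: int
    seed: int | None = None

    @property
    def n_sets(self) -> int:
        return len(self.counts)

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def sd(self) -> float:
        return float(np.std(self.counts, ddof=1)) if len(self.counts) > 1 else 0.0


def bh_significant_count(pvals: np.ndarray, alpha: float = 0.05) -> int:
    """Number of BH-significant p-values within one family."""
    return int(np.sum(adjust_bh(pvals) <= alpha))


def _rowwise_bh_counts(pmat: np.ndarray, alpha: float) -> np.ndarray:
    """BH-significant count per row, vectorized over rows.

    Missing p-values (NaN) shrink the family, matching ``adjust_bh``'s
    treatment of finite entries only.
    """
    n_rows, m = pmat.shape
    sorted_p = np.sort(pmat, axis=1)  # NaN sort to the end
    m_eff = np.sum(np.isfinite(pmat), axis=1)
    ranks = np.arange(1, m + 1)[None, :]
    with np.errstate(invalid="ignore"):
        passed = sorted_p <= ranks * alpha / np.maximum(m_eff, 1)[:, None]
    passed &= np.isfinite(sorted_p)
    # BH rejects everything up to the largest passing rank
    counts = np.zeros(n_rows, dtype=int)
    any_pass = passed.any(axis=1)
    if any_pass.any():
        last = m - 1 - np.argmax(passed[any_pass][:, ::-1], axis=1)
        counts[any_pass] = last + 1
    return counts


def sample_null_sets(
    gene_pvalues: pd.Series,
    set_size: int,
    n_sets: int = 100_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    exclude=(),
    method: str = "sample",
    chunk: int = 2_000,
) -> NullDistribution:
    """Null distribution of BH-significant counts over random gene sets.

    ``gene_pvalues`` holds the per-gene correlation p-value against the RBP
    over the whole expressed universe; ``exclude`` (typically the RBP's own
    gene) is removed from the universe before sampling.  ``method`` may be
    "sample" (uniform without replacement within each set, sets independent)
    or "exhaustive" (enumerate every subset; n_sets is ignored).
    """
    pv = gene_pvalues.drop(index=[g for g in exclude if g in gene_pvalues.index])
    universe = pv.to_numpy(dtype=float)
    n_universe = len(universe)
    if set_size > n_universe:
        raise EnrichmentError(
            f"set_size {set_size} exceeds universe size {n_universe}"
        )
    if method == "exhaustive":
        counts = np.array([
            _bh_count_single(universe[list(idx)], alpha)
            for idx in combinations(range(n_universe), set_size)
        ])
        return NullDistribution(counts=counts, set_size=set_size)
    if method != "sample":
        raise EnrichmentError(f"unknown sampling method {method!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(n_sets, dtype=int)
    done = 0
    while done < n_sets:
        take = min(chunk, n_sets - done)
        keys = rng.random((take, n_universe))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        pmat = universe[idx]
        out[done:done + take] = _rowwise_bh_counts(pmat, alpha)
        done += take
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return NullDistribution(counts=out, set_size=set_size, seed=seed_val)


def _bh_count_single(p: np.ndarray, alpha: float) -> int:
    p = p[np.isfinite(p)]
    if p.size == 0:
        return 0
    sp = np.sort(p)
    ranks = np.arange(1, len(sp) + 1)
    passing = np.nonzero(sp <= ranks * alpha / len(sp))[0]
    return int(passing[-1] + 1) if passing.size else 0


def empirical_pvalue(observed: int, null: NullDistribution) -> float:
    """p = #{null >= observed} / n_sets, floored at 1/n_sets.

    The floor reflects that a finite number of sampled sets cannot certify a
    p-value below the sampling resolution.
    """
    if null.n_sets == 0:
        raise EnrichmentError("empty null distribution")
    k = int(np.sum(null.counts >= observed))
    return max(k, 1) / null.n_sets


def glass_delta(observed: float, null: NullDistribution) -> float:
    """Glass' Delta: (observed - mean(null)) / sample sd(null)."""
    sd = null.sd
    if sd == 0:
        raise EnrichmentError("degenerate null (sd = 0); Delta undefined")
    return (observed - null.mean) / sd


@dataclass
class EnrichmentRecord:
    rbp: str
    trait: str
    n_targets: int
    observed: int
    null_mean: float
    null_sd: float
    emp_p: float
    glass_delta: float
    p_adj: float = np.nan


def enrichment_record(
    rbp: str,
    trait: str,
    target_pvalues: np.ndarray,
    null: NullDistribution,
    alpha: float = 0.05,
) -> EnrichmentRecord:
    observed = bh_significant_count(np.asarray(target_pvalues, dtype=float), alpha)
    emp_p = empirical_pvalue(observed, null)
    delta = glass_delta(observed, null) if null.sd > 0 else np.nan
    return EnrichmentRecord(
        rbp=rbp, trait=trait, n_targets=len(target_pvalues), observed=observed,
        null_mean=null.mean, null_sd=null.sd, emp_p=emp_p, glass_delta=delta,
    )


def classify_rbps(records: list[EnrichmentRecord], alpha: float = 0.05):
    """BH across RBPs per trait on empirical p; label mRNA-RBP / TE-RBP /
    multifunctional / none.  Returns (per-record table, per-RBP label table)."""
    tab = pd.DataFrame([vars(r) for r in records])
    if tab.empty:
        return tab, tab
    tab["p_adj"] = np.nan
    for trait, grp in tab.groupby("trait"):
        tab.loc[grp.index, "p_adj"] = adjust_bh(grp["emp_p"].to_numpy())
    wide = tab.pivot_table(index="rbp", columns="trait", values="p_adj")
    labels = []
    for rbp in wide.index:
        sig_mrna = bool(wide.loc[rbp].get("mRNA", np.nan) <= alpha)
        sig_te = bool(wide.loc[rbp].get("TE", np.nan) <= alpha)
        if sig_mrna and sig_te:
            lab = "multifunctional"
        elif sig_mrna:
            lab = "mRNA-RBP"
        elif sig_te:
            lab = "TE-RBP"
        else:
            lab = "none"
        labels.append({
            "rbp": rbp,
            "mrna_p_adj": wide.loc[rbp].get("mRNA", np.nan),
            "te_p_adj": wide.loc[rbp].get("TE", np.nan),
            "mrna_significant": sig_mrna,
            "te_significant": sig_te,
            "label": lab,
        })
    out = pd.DataFrame(labels).set_index("rbp")
    return tab, out


def target_overlap(mrna_targets: set, te_targets: set):
    """Venn counts and percent overlap (over the union) of the two target sets."""
    a, b = set(mrna_targets), set(te_targets)
    inter = a & b
    union = a | b
    venn = (len(a - b), len(inter), len(b - a))
    fraction = 100.0 * len(inter) / len(union) if union else np.nan
    return venn, fraction
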