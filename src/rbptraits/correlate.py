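"""Spearman correlation of RBP expression against target traits.

Correlations are pairwise-complete: each (RBP, gene) pair is evaluated over
the samples where both values are present.  The Spearman estimate uses
midranks; its p-value comes from the t approximation for n >= 10 and from
exhaustive permutation of the rank vector below that.  Benjamini-Hochberg
adjustment is applied within one RBP x one trait family (the RBP's CLIP
targets) by default.  Collinearity between co-expressed RBPs is handled by
rank-based partial correlation and Fisher-Z comparison of coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class CorrelationError(ValueError):
    pass


@dataclass
class CorrelationRecord:
    rbp: str
    gene: str
    trait: str
    rho: float
    n_pairs: int
    p: float
    p_adj: float = np.nan


def _t_sf(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return 2.0 * stats.t.sf(abs(t), df=n - 2)


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for small n (enumerate all n! orders)."""
    n = len(rx)
    sx = rx - rx.mean()
    denom = np.sqrt((sx * sx).sum())
    count = 0
    total = 0
    ry_c = ry - ry.mean()
    dy = np.sqrt((ry_c * ry_c).sum())
    target = abs(rho_obs) - 1e-12
    for perm in permutations(range(n)):
        r = float(sx @ ry_c[list(perm)]) / (denom * dy)
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def spearman(x, y, min_pairs: int = 10):
    """Pairwise-complete midrank Spearman.

    Returns (rho, p, n).  When fewer than ``min_pairs`` complete pairs exist
    the record is missing: (nan, nan, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < min_pairs:
        return np.nan, np.nan, n
    rx = stats.rankdata(x[mask])
    ry = stats.rankdata(y[mask])
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return np.nan, np.nan, n
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n >= 10:
        p = _t_sf(rho, n)
    else:
        p = _exact_perm_p(rx, ry, rho)
    return rho, p, n


def spearman_matrix(x: np.ndarray, trait: pd.DataFrame, min_pairs: int = 10):
    """Spearman of one expression vector against every row of a trait matrix.

    Vectorized fast path for rows without missing values; rows with missing
    entries (or a non-finite x sample) fall back to the pairwise routine.
    Returns a DataFrame with columns rho, p, n indexed like ``trait``.
    """
    x = np.asarray(x, dtype=float)
    mat = trait.to_numpy(dtype=float)
    n_genes, n_samples = mat.shape
    rho = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    npairs = np.zeros(n_genes, dtype=int)

    x_ok = np.isfinite(x)
    row_complete = np.isfinite(mat).all(axis=1)
    fast = row_complete & x_ok.all()

    if fast.any():
        rx = stats.rankdata(x)
        rx = (rx - rx.mean()) / rx.std()
        sub = mat[fast]
        rr = np.apply_along_axis(stats.rankdata, 1, sub)
        rr = rr - rr.mean(axis=1, keepdims=True)
        sd = rr.std(axis=1)
        good = sd > 0
        r = np.zeros(sub.shape[0])
        r[good] = (rr[good] @ rx) / (n_samples * sd[good])
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n_samples - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), df=n_samples - 2)
        p[np.abs(r) >= 1.0] = 0.0
        idx = np.where(fast)[0]
        rho[idx[good]] = r[good]
        pval[idx[good]] = p[good]
        npairs[idx] = n_samples

    for i in np.where(~fast)[0]:
        rho[i], pval[i], npairs[i] = spearman(x, mat[i], min_pairs=min_pairs)

    return pd.DataFrame({"rho": rho, "p": pval, "n": npairs}, index=trait.index)


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise CorrelationError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def correlate_rbp_targets(
    rbp: str,
    expression: pd.DataFrame,
    trait: pd.DataFrame,
    targets,
    trait_name: str,
    alpha: float = 0.05,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Correlation records of one RBP against its target genes for one trait.

    ``expression`` is the matrix the RBP row is read from (by convention the
    normalized Ribo-seq matrix).  BH adjustment is applied within this
    RBP x trait family.  Returns a long DataFrame with a ``significant``
    flag (p_adj <= alpha).
    """
    if rbp not in expression.index:
        raise CorrelationError(f"RBP {rbp!r} absent from expression matrix")
    targets = [g for g in targets if g in trait.index]
    cols = ["rbp", "gene", "trait", "rho", "n", "p", "p_adj", "significant"]
    if not targets:
        return pd.DataFrame(columns=cols)
    x = expression.loc[rbp].to_numpy(dtype=float)
    sub = trait.loc[targets]
    res = spearman_matrix(x, sub, min_pairs=min_pairs)
    res.insert(0, "trait", trait_name)
    res.insert(0, "gene", res.index)
    res.insert(0, "rbp", rbp)
    res["p_adj"] = adjust_bh(res["p"].to_numpy())
    res["significant"] = res["p_adj"] <= alpha
    return res.reset_index(drop=True)[cols]


def partial_correlation(x, y, z, min_pairs: int = 10):
    """Rank-based (Spearman-type) partial correlation of x and y given z.

    ``z`` is a vector or a (k, n) array of conditioning variables.  Computed
    as the correlation of residuals after regressing the rank-transformed
    x and y on the rank-transformed conditioning set.  p-value from a t
    distribution with n - 2 - k degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.atleast_2d(np.asarray(z, dtype=float))
    n_all = len(x)
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(Z).all(axis=0)
    n = int(mask.sum())
    k = Z.shape[0]
    if n - 3 <= k:
        raise CorrelationError(
            f"conditioning set of size {k} too large for n={n} complete pairs"
        )
    if n < min_pairs:
        return np.nan, np.nan, n
    rx = stats.rankdata(x[mask])
    ry = stats.rankdata(y[mask])
    rz = np.apply_along_axis(stats.rankdata, 1, Z[:, mask])
    design = np.column_stack([np.ones(n), rz.T])
    bx, *_ = np.linalg.lstsq(design, rx, rcond=None)
    by, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ bx
    ey = ry - design @ by
    sx = np.sqrt((ex * ex).sum())
    sy = np.sqrt((ey * ey).sum())
    if sx == 0 or sy == 0:
        return 0.0, 1.0, n
    r = float((ex @ ey) / (sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=df)
    return r, p, n


def first_order_partial(r_xy: float, r_xz: float, r_yz: float) -> float:
    """Closed-form first-order partial correlation."""
    denom = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    if denom == 0:
        raise CorrelationError("conditioning correlation of magnitude 1")
    return (r_xy - r_xz * r_yz) / denom


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int):
    """Compare two correlation coefficients via Fisher Z transformation."""
    for r in (r1, r2):
        if abs(r) >= 1:
            raise CorrelationError("|r| must be < 1 for the Z transform")
    if n1 <= 3 or n2 <= 3:
        raise CorrelationError("n must exceed 3")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def collinearity_filter(
    cluster_rbps: list[str],
    expression: pd.DataFrame,
    trait: pd.DataFrame,
    records: pd.DataFrame,
    alpha: float = 0.05,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Fraction of each cluster RBP's significant targets that stay
    significant after partialling out the other RBPs in the cluster.

    A target "remains" iff the BH-adjusted partial p (within the RBP's
    family) is <= alpha and the partial coefficient keeps the original sign.
    A cluster of one is an identity passthrough (fraction 1 where defined).
    """
    rows = []
    for rbp in cluster_rbps:
        sig = records[(records["rbp"] == rbp) & records["significant"]]
        if sig.empty:
            rows.append({"rbp": rbp, "n_targets": 0, "fraction_remaining": np.nan})
            continue
        others = [r for r in cluster_rbps if r != rbp and r in expression.index]
        if not others:
            rows.append({
                "rbp": rbp, "n_targets": len(sig), "fraction_remaining": 1.0,
            })
            continue
        x = expression.loc[rbp].to_numpy(dtype=float)
        Z = expression.loc[others].to_numpy(dtype=float)
        partials = []
        for _, rec in sig.iterrows():
            y = trait.loc[rec["gene"]].to_numpy(dtype=float)
            pr, pp, _ = partial_correlation(x, y, Z, min_pairs=min_pairs)
            partials.append((rec["gene"], rec["rho"], pr, pp))
        tab = pd.DataFrame(partials, columns=["gene", "rho", "partial_rho", "p"])
        tab["p_adj"] = adjust_bh(tab["p"].to_numpy())
        remains = (
            (tab["p_adj"] <= alpha)
            & (np.sign(tab["partial_rho"]) == np.sign(tab["rho"]))
        )
        rows.append({
            "rbp": rbp,
            "n_targets": len(tab),
            "fraction_remaining": float(remains.mean()),
        })
    return pd.DataFrame(rows)
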