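"""CLIP peak scoring, reproducibility (IDR), filtering and target assignment.

Each peak carries immunoprecipitation (IP) and size-matched input read
counts.  Peaks are scored by relative information content

    IC = p * log2(p / q),        p = (ip + 0.5) / ip_total,
                                 q = (input + 0.5) / input_total,

by fold enrichment FC = p/q, and by a one-sided binomial tail p-value for
the IP count at the input rate.  A 0.5 pseudocount is applied uniformly to
both read counts so that all three scores remain defined and depth-comparable
when either library has zero reads in the peak.

Replicate reproducibility is summarized by a simplified irreproducible
discovery rate (IDR): replicate scores are rank-transformed to normal scores
and fitted with a two-component Gaussian mixture (a reproducible component
with positive mean and correlation, an irreproducible component of
independent standard normals) by EM; the IDR of a peak is the cumulative
posterior probability of the irreproducible component.  This is a documented
reimplementation of the copula-mixture idea, not a numerical clone of the
reference IDR software.

Filtered peaks (IDR < 0.01, p <= 1e-5, FC > 8 by default, strict as stated)
are pooled across replicates/cell lines keeping the most significant peak
per overlapping group, and genes with at least one surviving peak on the
matching strand become the RBP's targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModels


class ClipError(ValueError):
    pass


class IdrConvergenceError(RuntimeError):
    def __init__(self, delta: float, n_iter: int):
        super().__init__(
            f"IDR EM did not converge after {n_iter} iterations "
            f"(last log-likelihood delta {delta:.3e})"
        )
        self.delta = delta


# ---------------------------------------------------------------------------
# per-peak scores


def score_information_content(
    ip_reads, input_reads, ip_total: float, input_total: float
):
    """Relative information content p*log2(p/q) with 0.5 pseudocounts."""
    ip = np.asarray(ip_reads, dtype=float)
    inp = np.asarray(input_reads, dtype=float)
    if (ip < 0).any() or (inp < 0).any():
        raise ClipError("read counts must be non-negative")
    if ip_total <= 0 or input_total <= 0:
        raise ClipError("library totals must be positive")
    p = (ip + 0.5) / ip_total
    q = (inp + 0.5) / input_total
    return p * np.log2(p / q)


def peak_enrichment(ip_reads, input_reads, ip_total: float, input_total: float):
    """Fold change and one-sided binomial enrichment p-value.

    FC uses the pseudocounted fractions; the p-value is the upper binomial
    tail P(X >= ip) with X ~ Binomial(ip_total, q) at the pseudocounted
    input rate q.
    """
    ip = np.asarray(ip_reads, dtype=float)
    inp = np.asarray(input_reads, dtype=float)
    if ip_total <= 0 or input_total <= 0:
        raise ClipError("library totals must be positive")
    if (ip < 0).any() or (inp < 0).any():
        raise ClipError("read counts must be non-negative")
    p_hat = (ip + 0.5) / ip_total
    q_hat = (inp + 0.5) / input_total
    fc = p_hat / q_hat
    rate = np.clip(q_hat, 0.0, 1.0)
    pval = stats.binom.sf(np.round(ip).astype(int) - 1, int(ip_total), rate)
    return fc, pval


# ---------------------------------------------------------------------------
# IDR


def _normal_scores(scores: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(scores, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(scores))


def compute_idr(
    scores_rep1,
    scores_rep2,
    tol: float = 1e-6,
    max_iter: int = 500,
    init_rho: float = 0.8,
    init_pi: float = 0.5,
):
    """IDR per matched peak from two replicate score vectors.

    Returns an array of global IDR values (cumulative average of the local
    irreproducibility posteriors in order of decreasing reproducibility),
    which is monotone non-decreasing in rank discordance.
    """
    s1 = np.asarray(scores_rep1, dtype=float)
    s2 = np.asarray(scores_rep2, dtype=float)
    if s1.shape != s2.shape:
        raise ClipError("replicate score vectors must have equal length")
    n = len(s1)
    if n < 20:
        raise ClipError("IDR requires at least 20 matched peaks")
    if np.ptp(s1) == 0 or np.ptp(s2) == 0:
        raise ClipError("constant scores carry no ranking information")

    z1 = _normal_scores(s1)
    z2 = _normal_scores(s2)

    pi = float(init_pi)
    mu = 1.0
    sigma2 = 1.0
    rho = float(init_rho)
    loglik = -np.inf
    delta = np.inf

    def log_bvn(z1, z2, mu, sigma2, rho):
        det = sigma2 * sigma2 * (1 - rho**2)
        a = (z1 - mu) ** 2 + (z2 - mu) ** 2
        b = 2 * rho * (z1 - mu) * (z2 - mu)
        quad = (a - b) / (sigma2 * (1 - rho**2))
        return -np.log(2 * np.pi) - 0.5 * np.log(det) - 0.5 * quad

    log_noise = (
        -np.log(2 * np.pi) - 0.5 * (z1**2 + z2**2)
    )  # independent standard normals

    for it in range(max_iter):
        log_rep = log_bvn(z1, z2, mu, sigma2, rho) + np.log(pi)
        log_irr = log_noise + np.log1p(-pi)
        m = np.maximum(log_rep, log_irr)
        denom = m + np.log(np.exp(log_rep - m) + np.exp(log_irr - m))
        gamma = np.exp(log_rep - denom)  # responsibility of reproducible comp.

        new_loglik = float(np.sum(denom))
        delta = abs(new_loglik - loglik)
        loglik = new_loglik

        w = gamma.sum()
        pi = float(np.clip(w / n, 1e-4, 1 - 1e-4))
        if w > 1e-12:
            mu = float(np.sum(gamma * (z1 + z2)) / (2 * w))
            d1 = z1 - mu
            d2 = z2 - mu
            sigma2 = float(np.sum(gamma * (d1**2 + d2**2)) / (2 * w))
            sigma2 = max(sigma2, 1e-3)
            rho = float(np.sum(gamma * d1 * d2) / (w * sigma2))
            rho = float(np.clip(rho, 0.0, 0.999))
        if delta < tol:
            break
    else:
        raise IdrConvergenceError(delta, max_iter)

    log_rep = log_bvn(z1, z2, mu, sigma2, rho) + np.log(pi)
    log_irr = log_noise + np.log1p(-pi)
    m = np.maximum(log_rep, log_irr)
    denom = m + np.log(np.exp(log_rep - m) + np.exp(log_irr - m))
    local_idr = np.exp(log_irr - denom)

    order = np.argsort(local_idr, kind="stable")
    csum = np.cumsum(local_idr[order])
    global_idr_sorted = csum / np.arange(1, n + 1)
    # cumulative mean of a sorted sequence is already non-decreasing
    global_idr = np.empty(n)
    global_idr[order] = np.minimum(global_idr_sorted, 1.0)
    return global_idr


# ---------------------------------------------------------------------------
# filtering / pooling


def filter_peaks(
    peaks: pd.DataFrame,
    idr_max: float = 0.01,
    p_max: float = 1e-5,
    fc_min: float = 8.0,
) -> pd.DataFrame:
    """Keep peaks with idr < idr_max AND p <= p_max AND FC > fc_min.

    The inequalities are exactly the published ones: IDR strictly below the
    cutoff, p at-or-below, fold change strictly above.
    """
    keep = (
        (peaks["idr"] < idr_max)
        & (peaks["enrichment_p"] <= p_max)
        & (peaks["fold_change"] > fc_min)
    )
    return peaks.loc[keep].copy()


def pool_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Collapse same-strand overlapping peaks to the most significant one.

    Overlap (>= 1 shared base on the same chromosome and strand) is chained
    by single linkage; each connected component keeps the peak with the
    smallest enrichment p, ties broken by larger information content, then
    by leftmost start.
    """
    if peaks.empty:
        return peaks.copy()
    if (peaks["end"] <= peaks["start"]).any():
        raise ClipError("malformed interval: end must exceed start")
    kept = []
    for (_, _), grp in peaks.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values(["start", "end"], kind="stable")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        comp_start = 0
        reach = ends[0]
        boundaries = []
        for i in range(1, len(grp)):
            if starts[i] >= reach:  # half-open: touching does not overlap
                boundaries.append((comp_start, i))
                comp_start = i
            reach = max(reach, ends[i])
        boundaries.append((comp_start, len(grp)))
        for lo, hi in boundaries:
            comp = grp.iloc[lo:hi]
            best = comp.sort_values(
                by=["enrichment_p", "information_content", "start"],
                ascending=[True, False, True],
                kind="stable",
            ).iloc[0]
            kept.append(best)
    out = pd.DataFrame(kept).reset_index(drop=True)
    return out.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# target assignment

REGIONS = ["CDS", "5UTR", "3UTR", "intron"]
_REGION_PRIORITY = {"CDS": 0, "5UTR": 1, "3UTR": 2, "intron": 3}


@dataclass
class TargetSet:
    rbp: str
    genes: set
    region_proportions: pd.DataFrame  # genes x REGIONS, rows sum to 1
    skipped_chroms: int = 0


def assign_targets(peaks: pd.DataFrame, models: GeneModels) -> TargetSet:
    """Derive the target gene set of one RBP from its pooled filtered peaks.

    A gene is a target iff >= 1 peak overlaps one of its transcripts on the
    matching strand.  Each peak is assigned a single mRNA region by its
    midpoint with priority CDS > 5'UTR > 3'UTR > intron across transcripts.
    Peaks on chromosomes absent from the annotation are skipped and counted.
    """
    rbps = peaks["rbp"].unique() if "rbp" in peaks.columns else ["?"]
    if len(rbps) > 1:
        raise ClipError("assign_targets expects peaks of a single RBP")
    rbp = rbps[0] if len(rbps) else "?"

    genes: set = set()
    region_counts: dict[str, np.ndarray] = {}
    skipped = 0
    for row in peaks.itertuples(index=False):
        if row.chrom not in models.chroms:
            skipped += 1
            continue
        hits = models.overlapping_transcripts(
            row.chrom, row.start, row.end, row.strand
        )
        if not hits:
            continue
        midpoint = row.start + (row.end - row.start) // 2
        best_region = None
        hit_genes = set()
        for tx in hits:
            hit_genes.add(tx.gene_id)
            region = models.region_at(tx, midpoint)
            if region is not None and (
                best_region is None
                or _REGION_PRIORITY[region] < _REGION_PRIORITY[best_region]
            ):
                best_region = region
        genes |= hit_genes
        if best_region is not None:
            # attribute the region call to every overlapped gene
            for g in hit_genes:
                counts = region_counts.setdefault(g, np.zeros(len(REGIONS)))
                counts[REGIONS.index(best_region)] += 1

    if region_counts:
        tab = pd.DataFrame.from_dict(region_counts, orient="index", columns=REGIONS)
        tab = tab.div(tab.sum(axis=1), axis=0)
    else:
        tab = pd.DataFrame(columns=REGIONS)
    tab.index.name = "gene_id"
    return TargetSet(rbp=rbp, genes=genes, region_proportions=tab.sort_index(),
                     skipped_chroms=skipped)
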