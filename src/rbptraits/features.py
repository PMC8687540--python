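"""Target characterization: clustering, lengths, 5'UTR structure, ubiquity.

Groups of targets are compared with the Wilcoxon rank-sum test (exact when
both groups are small and tie-free, normal approximation with tie correction
otherwise).  Correlation-profile clustering uses Euclidean distances with
complete linkage; RBP-RBP target-set similarity uses 1 - Jaccard with
average linkage.  5'UTR structure comparisons operate on length-normalized
minimum free energy and can be protected against length confounding by
decile-stratified subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .correlate import adjust_bh
from .fold import fold_mfe, normalized_mfe


class FeatureError(ValueError):
    pass


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix (merge order + heights)
    labels: list  # leaf ids in input order
    metric: str
    method: str

    def flat_labels(self, n_clusters: int) -> pd.Series:
        flat = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")


def cluster_correlation_matrix(
    rho: pd.DataFrame, method: str = "complete"
) -> ClusterResult:
    """Hierarchical clustering of RBP correlation profiles (rows).

    Missing correlations are imputed as 0 for the distance computation only.
    """
    if rho.shape[0] < 2:
        raise FeatureError("need at least 2 rows to cluster")
    mat = rho.fillna(0.0).to_numpy(dtype=float)
    dist = pdist(mat, metric="euclidean")
    Z = hierarchy.linkage(dist, method=method)
    return ClusterResult(
        linkage=Z, labels=list(rho.index), metric="euclidean", method=method
    )


def jaccard_distance(a: set, b: set) -> float:
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def rbp_overlap_dendrogram(target_sets: dict[str, set], method: str = "average") -> ClusterResult:
    """Cluster RBPs on 1 - Jaccard similarity of their target gene sets."""
    names = sorted(target_sets)
    if len(names) < 2:
        raise FeatureError("need at least 2 RBPs")
    if all(len(target_sets[n]) == 0 for n in names):
        raise FeatureError("all target sets are empty")
    n = len(names)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = jaccard_distance(target_sets[names[i]], target_sets[names[j]])
            dmat[i, j] = dmat[j, i] = d
    Z = hierarchy.linkage(squareform(dmat, checks=False), method=method)
    return ClusterResult(linkage=Z, labels=names, metric="1-jaccard", method=method)


def select_principal_isoform(
    transcript_lengths: pd.DataFrame, expression: pd.Series
) -> pd.Series:
    """Per gene, the transcript with highest mean expression.

    ``transcript_lengths`` has columns gene_id, transcript_id, length;
    ``expression`` maps transcript_id -> abundance proxy.  Ties go to the
    longer transcript, then to the lexicographically first id.
    """
    tab = transcript_lengths.copy()
    tab["expr"] = tab["transcript_id"].map(expression).fillna(0.0)
    out = {}
    for gene, grp in tab.groupby("gene_id"):
        if grp.empty:
            continue
        best = grp.sort_values(
            by=["expr", "length", "transcript_id"],
            ascending=[False, False, True],
            kind="stable",
        ).iloc[0]
        out[gene] = best["transcript_id"]
    if not out:
        raise FeatureError("no transcripts available")
    return pd.Series(out, name="principal_transcript").sort_index()


def rank_sum_test(a, b):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney).

    Exact when min(n, m) <= 8 and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction.
    Returns (U statistic of the first group, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise FeatureError("empty group in rank-sum test")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_lengths(group_a, group_b):
    """Wilcoxon rank-sum comparison of two groups of feature lengths.

    Each group must contain at least 3 values.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise FeatureError("each group needs >= 3 genes")
    return rank_sum_test(a, b)


def isoform_te_compare(te_isoform1, te_isoform2):
    """Rank-sum comparison of two per-isoform TE vectors across samples."""
    a = np.asarray(te_isoform1, dtype=float)
    b = np.asarray(te_isoform2, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise FeatureError("each isoform needs >= 3 samples")
    return rank_sum_test(a, b)


def utr_mfe_table(
    sequences: dict[str, str], min_length: int = 20, engine=fold_mfe
) -> pd.DataFrame:
    """Per-gene 5'UTR MFE and length-normalized MFE.

    Sequences shorter than ``min_length`` are kept in the table but flagged
    (``evaluable`` = False) and excluded from group comparisons.
    """
    rows = []
    for gene in sorted(sequences):
        seq = sequences[gene]
        mfe = engine(seq)
        rows.append({
            "gene_id": gene,
            "utr5_length": len(seq),
            "mfe": mfe,
            "normalized_mfe": mfe / len(seq) if len(seq) else np.nan,
            "evaluable": len(seq) >= min_length,
        })
    return pd.DataFrame(rows).set_index("gene_id")


def compare_mfe_by_sign(
    mfe_table: pd.DataFrame, positive_genes, negative_genes
):
    """Rank-sum on normalized MFE between positively and negatively
    correlating targets.  Returns (U, p, n_pos, n_neg); missing (nan p)
    when either sign group has < 3 evaluable members."""
    tab = mfe_table[mfe_table["evaluable"]]
    pos = tab.loc[tab.index.intersection(list(positive_genes)), "normalized_mfe"]
    neg = tab.loc[tab.index.intersection(list(negative_genes)), "normalized_mfe"]
    if len(pos) < 3 or len(neg) < 3:
        return np.nan, np.nan, len(pos), len(neg)
    w, p = rank_sum_test(pos.to_numpy(), neg.to_numpy())
    return w, p, len(pos), len(neg)


def compare_mfe_batch(
    mfe_table: pd.DataFrame, sign_groups: dict[str, tuple]
) -> pd.DataFrame:
    """Batched MFE comparisons across RBPs with BH adjustment."""
    rows = []
    for rbp, (pos, neg) in sorted(sign_groups.items()):
        w, p, n_pos, n_neg = compare_mfe_by_sign(mfe_table, pos, neg)
        rows.append({"rbp": rbp, "W": w, "p": p, "n_pos": n_pos, "n_neg": n_neg})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = adjust_bh(out["p"].to_numpy())
    return out


def length_matched_subsample(
    groups: dict[str, pd.Series],
    n_per_group: int = 50,
    n_bins: int = 10,
    seed: int | np.random.Generator | None = None,
    max_attempts: int = 100,
    balance_p: float = 0.1,
):
    """Subsample each group to ``n_per_group`` members with matched length
    distributions.

    ``groups`` maps group name -> Series of lengths indexed by gene id.
    Sampling is stratified on deciles of the pooled length distribution;
    strata with insufficient members donate their quota to adjacent bins.
    The subsample is accepted once every pairwise rank-sum p on lengths
    exceeds ``balance_p``; up to ``max_attempts`` redraws are made.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = sorted(groups)
    for name in names:
        if len(groups[name]) < n_per_group:
            raise FeatureError(
                f"group {name!r} has fewer than {n_per_group} members"
            )
    pooled = pd.concat([groups[n] for n in names])
    edges = np.quantile(pooled.to_numpy(), np.linspace(0, 1, n_bins + 1))
    edges[0] -= 1e-9
    edges = np.unique(edges)
    quota = _bin_quota(pooled, edges, n_per_group)

    for _ in range(max_attempts):
        sampled = {}
        for name in names:
            sampled[name] = _stratified_draw(groups[name], edges, quota, rng)
        ps = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                _, p = rank_sum_test(
                    groups[names[i]].loc[sampled[names[i]]].to_numpy(),
                    groups[names[j]].loc[sampled[names[j]]].to_numpy(),
                )
                ps.append(p)
        if all(p > balance_p for p in ps):
            return sampled
    raise FeatureError(
        f"could not balance length distributions in {max_attempts} attempts"
    )


def _bin_quota(pooled: pd.Series, edges: np.ndarray, n_total: int) -> np.ndarray:
    counts, _ = np.histogram(pooled.to_numpy(), bins=edges)
    frac = counts / counts.sum()
    quota = np.floor(frac * n_total).astype(int)
    remainder = n_total - quota.sum()
    order = np.argsort(-(frac * n_total - quota))
    for k in order[:remainder]:
        quota[k] += 1
    return quota


def _stratified_draw(
    lengths: pd.Series, edges: np.ndarray, quota: np.ndarray,
    rng: np.random.Generator,
) -> list:
    bins = np.digitize(lengths.to_numpy(), edges[1:-1], right=True)
    chosen: list = []
    deficit = 0
    for b in range(len(quota)):
        members = lengths.index[bins == b]
        want = quota[b] + deficit
        take = min(want, len(members))
        deficit = want - take
        if take > 0:
            chosen.extend(rng.choice(members, size=take, replace=False))
    if deficit > 0:  # merge leftovers into whatever remains anywhere
        rest = lengths.index.difference(pd.Index(chosen))
        chosen.extend(rng.choice(rest, size=deficit, replace=False))
    return chosen


def classify_ubiquity(
    tpm: pd.DataFrame, detect: float = 1.0, high: float = 10.0,
    min_tissues: int = 30,
) -> pd.DataFrame:
    """Ubiquitous expression flag per gene from a tissue-averaged TPM table.

    Ubiquitous iff strictly more than ``min_tissues`` tissues show TPM >=
    ``high``.  Also reports the number of tissues at the detection level.
    """
    if tpm.shape[1] < 1:
        raise FeatureError("need at least one tissue column")
    n_high = (tpm >= high).sum(axis=1)
    n_detect = (tpm >= detect).sum(axis=1)
    return pd.DataFrame({
        "n_tissues_detected": n_detect,
        "n_tissues_high": n_high,
        "ubiquitous": n_high > min_tissues,
    })
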