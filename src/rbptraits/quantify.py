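"""Joint normalization, expression filtering, translational efficiency and PSI.

Ribo-seq and RNA-seq libraries are normalized together with a single
median-of-ratios size-factor fit, because translational efficiency (TE) is a
ratio between the two assays and only a joint scale makes that ratio
comparable across samples.  TE for gene g in sample s is

    TE[g, s] = ribo_norm[g, s] / rna_norm[g, s]

and is left missing wherever the normalized RNA value is zero.  PSI for a
cassette exon is the averaged flanking inclusion-junction coverage over total
junction coverage, with a configurable floor on total coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class QuantificationError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Genes x libraries of raw counts for one assay (RNA or RIBO)."""

    counts: pd.DataFrame
    assay: str  # "RNA" | "RIBO"
    size_factors: pd.Series | None = None
    feature_lengths: pd.Series | None = None  # nt, CDS length by convention

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise QuantificationError("counts must be non-negative")
        if self.assay not in ("RNA", "RIBO"):
            raise QuantificationError(f"unknown assay label {self.assay!r}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise QuantificationError("size factors not set; run normalization")
        return normalize(self.counts, self.size_factors)


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over the given libraries (columns).

    Pass the horizontal concatenation of the RNA and Ribo count matrices to
    normalize the two assays jointly.  Genes with a zero count in any library
    are excluded from the geometric-mean reference (standard convention).
    """
    mat = counts.to_numpy(dtype=float)
    if mat.size == 0:
        raise QuantificationError("empty count matrix")
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise QuantificationError(
            "no gene has a nonzero count in every library; "
            "size factors are undefined"
        )
    ref = mat[nonzero]
    log_geomean = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each library (column) by its size factor."""
    sf = size_factors.reindex(counts.columns)
    if sf.isna().any():
        raise QuantificationError("size factor missing for some libraries")
    if (sf <= 0).any():
        raise QuantificationError("size factors must be strictly positive")
    return counts / sf


def compute_fpkm(
    counts: pd.DataFrame,
    feature_lengths: pd.Series,
    library_totals: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM = count / ((length/1e3) * (library_total/1e6)).

    Feature length is the CDS length when counting was CDS-restricted.
    Library totals default to the column sums of ``counts``.
    """
    if library_totals is None:
        library_totals = counts.sum(axis=0)
    lengths = feature_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise QuantificationError("feature lengths must be positive for all genes")
    if (library_totals <= 0).any():
        raise QuantificationError("zero library total")
    per_kb = counts.div(lengths / 1e3, axis=0)
    return per_kb.div(library_totals / 1e6, axis=1)


def filter_expressed(
    fpkm: pd.DataFrame,
    rna_counts: pd.DataFrame,
    ribo_counts: pd.DataFrame,
    min_mean_fpkm: float = 1.0,
    min_samples: int = 20,
) -> pd.Index:
    """Genes kept iff mean FPKM strictly exceeds ``min_mean_fpkm`` and both
    assays have at least one read in at least ``min_samples`` samples."""
    if not (fpkm.index.equals(rna_counts.index) and fpkm.index.equals(ribo_counts.index)):
        raise QuantificationError("matrices must share gene ids")
    n_samples = rna_counts.shape[1]
    if min_samples > n_samples:
        raise QuantificationError(
            f"min_samples={min_samples} exceeds cohort size {n_samples}"
        )
    mean_ok = fpkm.mean(axis=1) > min_mean_fpkm
    both = ((rna_counts >= 1) & (ribo_counts >= 1)).sum(axis=1) >= min_samples
    return fpkm.index[mean_ok & both]


def compute_te(ribo_norm: pd.DataFrame, rna_norm: pd.DataFrame) -> pd.DataFrame:
    """Elementwise Ribo/RNA ratio; missing where RNA is zero."""
    if ribo_norm.shape != rna_norm.shape or not ribo_norm.index.equals(rna_norm.index):
        raise QuantificationError("ribo and rna matrices must be aligned")
    rna = rna_norm.to_numpy(dtype=float)
    ribo = ribo_norm.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        te = np.where(rna > 0, ribo / rna, np.nan)
    return pd.DataFrame(te, index=ribo_norm.index, columns=ribo_norm.columns)


def compute_psi(
    ij_up: np.ndarray | pd.DataFrame,
    ij_down: np.ndarray | pd.DataFrame,
    ej: np.ndarray | pd.DataFrame,
    min_total: float = 10,
):
    """PSI = mean(IJ_up, IJ_down) / (mean(IJ_up, IJ_down) + EJ).

    Missing when mean inclusion + exclusion coverage falls below
    ``min_total`` (avoids unstable 0/0 estimates at low depth).
    """
    up = np.asarray(ij_up, dtype=float)
    down = np.asarray(ij_down, dtype=float)
    ex = np.asarray(ej, dtype=float)
    if (up < 0).any() or (down < 0).any() or (ex < 0).any():
        raise QuantificationError("junction counts must be non-negative")
    inc = (up + down) / 2.0
    total = inc + ex
    with np.errstate(divide="ignore", invalid="ignore"):
        psi = np.where(total >= min_total, inc / total, np.nan)
    if isinstance(ij_up, pd.DataFrame):
        return pd.DataFrame(psi, index=ij_up.index, columns=ij_up.columns)
    return psi


def psi_matrix_from_junctions(junctions: pd.DataFrame, min_total: float = 10) -> pd.DataFrame:
    """Pivot a long junction table into a (gene, exon) x sample PSI matrix."""
    tab = junctions.copy()
    tab["psi"] = compute_psi(
        tab["ij_up"].to_numpy(), tab["ij_down"].to_numpy(), tab["ej"].to_numpy(),
        min_total=min_total,
    )
    wide = tab.pivot_table(
        index=["gene_id", "exon_id"], columns="sample", values="psi", dropna=False
    )
    return wide
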