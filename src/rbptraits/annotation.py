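"""In-memory gene models with interval queries.

The on-disk convention is GTF: 1-based, inclusive.  Internally everything is
0-based half-open so that BED peaks compare directly.  ``GeneModels`` indexes
transcript spans per (chromosome, strand) with interval trees and answers the
two questions target assignment needs: which transcripts does an interval
overlap, and which mRNA region (5'UTR / CDS / 3'UTR / intron) contains a
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

FEATURES = ("transcript", "exon", "five_prime_utr", "CDS", "three_prime_utr")

_REGION_OF_FEATURE = {
    "five_prime_utr": "5UTR",
    "CDS": "CDS",
    "three_prime_utr": "3UTR",
}


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open span
    end: int
    exons: list = field(default_factory=list)  # [(start, end)] 0-based
    regions: dict = field(default_factory=dict)  # region -> [(start, end)]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


class GeneModels:
    """Queryable set of transcript models built from a flat GTF-like table."""

    def __init__(self, transcripts: list[Transcript]):
        self.transcripts = {t.transcript_id: t for t in transcripts}
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        by_gene: dict[str, list[Transcript]] = {}
        for t in transcripts:
            key = (t.chrom, t.strand)
            self._trees.setdefault(key, IntervalTree())
            self._trees[key].addi(t.start, t.end, t)
            by_gene.setdefault(t.gene_id, []).append(t)
        self.by_gene = by_gene
        self.chroms = {t.chrom for t in transcripts}

    @classmethod
    def from_table(cls, ann: pd.DataFrame) -> "GeneModels":
        """Build from the annotation table (GTF convention: 1-based inclusive)."""
        txs: dict[str, Transcript] = {}
        for row in ann.itertuples(index=False):
            tx_id = row.transcript_id
            if tx_id is None or (isinstance(tx_id, float) and pd.isna(tx_id)):
                continue
            start0, end0 = int(row.start) - 1, int(row.end)
            if row.feature == "transcript":
                txs[tx_id] = Transcript(
                    transcript_id=tx_id, gene_id=row.gene_id, chrom=row.chrom,
                    strand=row.strand, start=start0, end=end0,
                )
        for row in ann.itertuples(index=False):
            tx_id = row.transcript_id
            if tx_id not in txs:
                continue
            tx = txs[tx_id]
            start0, end0 = int(row.start) - 1, int(row.end)
            if row.feature == "exon":
                tx.exons.append((start0, end0))
            elif row.feature in _REGION_OF_FEATURE:
                tx.regions.setdefault(_REGION_OF_FEATURE[row.feature], []).append(
                    (start0, end0)
                )
        for tx in txs.values():
            tx.exons.sort()
            for iv in tx.regions.values():
                iv.sort()
        return cls(list(txs.values()))

    def genes(self) -> list[str]:
        return sorted(self.by_gene)

    def overlapping_transcripts(
        self, chrom: str, start: int, end: int, strand: str
    ) -> list[Transcript]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(start, end)),
            key=lambda t: t.transcript_id,
        )

    @staticmethod
    def region_at(tx: Transcript, pos: int) -> str | None:
        """Region containing a 0-based position, or None if outside the span."""
        if not (tx.start <= pos < tx.end):
            return None
        for region in ("CDS", "5UTR", "3UTR"):
            for s, e in tx.regions.get(region, ()):
                if s <= pos < e:
                    return region
        for s, e in tx.exons:
            if s <= pos < e:
                return None  # exonic but outside annotated mRNA regions
        return "intron"

    def feature_lengths(self, region: str = "CDS") -> pd.Series:
        """Per-gene length (nt) of a region, max over the gene's transcripts."""
        out = {}
        for gene, txs in self.by_gene.items():
            lengths = [
                sum(e - s for s, e in t.regions.get(region, ())) for t in txs
            ]
            out[gene] = max(lengths) if lengths else 0
        return pd.Series(out, name=f"{region}_length").sort_index()
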