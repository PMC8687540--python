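"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts and trait matrices travel as TSV (genes x samples with a header of
sample ids), CLIP peaks as BED6+ (0-based half-open), gene models as a
GTF-like 9-column table (1-based inclusive), and 5'UTR sequences as FASTA.
Every writer here round-trips through the matching reader byte-stably.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "ip_reads", "input_reads", "ip_total", "input_total",
]

GTF_COLUMNS = [
    "seqname", "source", "feature", "start", "end",
    "score", "strand", "frame", "attribute",
]


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples count/trait matrix (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_bed_peaks(path: str | Path) -> pd.DataFrame:
    """Read BED6+ CLIP peaks.

    The ``name`` column is ``rbp:replicate``; it is split into ``rbp`` and
    ``replicate`` columns for convenience.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)
    if (df["end"] <= df["start"]).any():
        raise ValueError("malformed BED interval: end must exceed start")
    parts = df["name"].str.split(":", n=1, expand=True)
    df["rbp"] = parts[0]
    df["replicate"] = parts[1]
    return df


def write_bed_peaks(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    if "name" not in out.columns:
        out["name"] = out["rbp"].astype(str) + ":" + out["replicate"].astype(str)
    if "score" not in out.columns:
        out["score"] = 0
    out[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def _format_attributes(row: pd.Series) -> str:
    attrs = [f'gene_id "{row["gene_id"]}"']
    tx = row.get("transcript_id")
    if isinstance(tx, str) and tx:
        attrs.append(f'transcript_id "{tx}"')
    return "; ".join(attrs) + ";"


def write_gtf(ann: pd.DataFrame, path: str | Path) -> None:
    """Write an annotation table as GTF (1-based inclusive coordinates).

    Expects columns: chrom, source?, feature, start, end, strand,
    gene_id, transcript_id.
    """
    rows = []
    for _, r in ann.iterrows():
        rows.append("\t".join([
            str(r["chrom"]),
            str(r.get("source", "rbptraits")),
            str(r["feature"]),
            str(int(r["start"])),
            str(int(r["end"])),
            ".",
            str(r["strand"]),
            ".",
            _format_attributes(r),
        ]))
    Path(path).write_text("\n".join(rows) + "\n")


def _parse_attributes(attr: str) -> dict:
    out = {}
    for field in attr.strip().split(";"):
        field = field.strip()
        if not field:
            continue
        key, _, value = field.partition(" ")
        out[key] = value.strip('"')
    return out


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Read a GTF-like file into the flat annotation table used internally."""
    raw = pd.read_csv(
        path, sep="\t", header=None, names=GTF_COLUMNS, comment="#",
        dtype={"seqname": str},
    )
    attrs = raw["attribute"].map(_parse_attributes)
    df = pd.DataFrame({
        "chrom": raw["seqname"],
        "feature": raw["feature"],
        "start": raw["start"].astype(int),
        "end": raw["end"].astype(int),
        "strand": raw["strand"],
        "gene_id": [a.get("gene_id") for a in attrs],
        "transcript_id": [a.get("transcript_id") for a in attrs],
    })
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_junctions_tsv(path: str | Path) -> pd.DataFrame:
    """Junction counts: columns gene_id, exon_id, sample, ij_up, ij_down, ej."""
    return pd.read_csv(path, sep="\t")


def write_junctions_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
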