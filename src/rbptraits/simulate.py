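"""Synthetic cohort generator with a planted regulatory truth table.

The generator emulates the statistical structure the analysis assumes for a
matched Ribo-seq / RNA-seq cohort:

* RBP expression is lognormal across samples; the standardized per-sample
  latent ``z`` of each RBP is the regulatory dose.
* For a planted target, the log mean mRNA abundance and/or log translational
  efficiency shift by ``effect_size * sign * z`` (effects from several RBPs
  add on the log scale).
* RNA counts are negative binomial around sizefactor * mu; Ribo counts
  around sizefactor * mu * TE, with a common dispersion.
* CLIP experiments report peaks for the truly bound genes (with replicated,
  correlated read enrichment) plus input-like decoy peaks on other genes at
  a configurable false-positive rate; bound genes are missed at a
  false-negative rate.
* 5'UTR sequences are emitted per gene as "structured" (palindromic GC-rich
  stems) or "unstructured" (pairing-poor composition).
* Cassette-exon inclusion (PSI) can be coupled to an RBP's dose, together
  with a TE offset between inclusion and exclusion isoforms.

Every product is a plain-text table that round-trips through
:mod:`rbptraits.io`, and every draw flows from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModels
from .quantify import CountMatrix


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration

DEFAULT_LENGTH_PARAMS = {
    # lognormal (meanlog, sdlog) of region lengths in nt, and exon count
    "utr5": (np.log(120.0), 0.5),
    "cds": (np.log(1500.0), 0.7),
    "utr3": (np.log(500.0), 0.6),
    "intron": (np.log(800.0), 0.6),
    "n_exons_mean": 4.0,  # exon count = 1 + Poisson(n_exons_mean - 1)
}


@dataclass(frozen=True)
class RbpSpec:
    """One simulated RBP: its trait, target-set size, and effect."""

    name: str
    trait: str  # "mRNA" | "TE" | "both" | "null"
    n_targets: int = 100
    effect_size: float = 1.0
    effect_sign: str | int = "random"  # "random", +1 or -1
    overlap_fraction: float = 0.0  # shared targets between traits ("both")

    def __post_init__(self):
        if self.trait not in ("mRNA", "TE", "both", "null"):
            raise SimulationError(f"unknown trait {self.trait!r}")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise SimulationError("overlap_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level generative settings.

    Defaults mirror the cohort scale the analysis is designed for: 80
    samples, a few thousand expressed genes, unit effect sizes on the log
    scale and moderate negative-binomial dispersion.
    """

    n_genes: int = 2000
    n_samples: int = 80
    rbps: tuple = ()
    dispersion: float = 0.1
    library_size_range: tuple = (400_000, 600_000)
    clip_fp_rate: float = 0.02
    clip_fn_rate: float = 0.1
    clip_replicates: int = 2
    gene_log_mean: float = float(np.log(150.0))
    gene_log_sd: float = 1.0
    te_log_sd: float = 0.25
    rbp_log_sd: float = 0.5
    length_params: dict = field(default_factory=lambda: dict(DEFAULT_LENGTH_PARAMS))
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_samples <= 0:
            raise SimulationError("n_genes and n_samples must be positive")
        if self.dispersion <= 0:
            raise SimulationError("dispersion must be > 0")
        for rate in (self.clip_fp_rate, self.clip_fn_rate):
            if not (0.0 <= rate <= 1.0):
                raise SimulationError("CLIP error rates must lie in [0, 1]")
        for spec in self.rbps:
            if spec.n_targets > self.n_genes:
                raise SimulationError(
                    f"{spec.name}: n_targets exceeds n_genes"
                )

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


def default_panel(
    n_per_class: int = 6,
    n_targets: int = 100,
    effect_size: float = 1.0,
) -> tuple:
    """The standard benchmarking panel: equal numbers of mRNA-only, TE-only,
    dual (disjoint target sets) and null RBPs."""
    specs = []
    idx = 1
    for trait in ("mRNA", "TE", "both", "null"):
        for _ in range(n_per_class):
            specs.append(RbpSpec(
                name=f"RBP{idx:02d}", trait=trait, n_targets=n_targets,
                effect_size=effect_size,
            ))
            idx += 1
    return tuple(specs)


# ---------------------------------------------------------------------------
# truth


@dataclass
class SimTruth:
    """Planted regulatory map against which recovery is scored."""

    traits: dict  # rbp -> trait label
    mrna_targets: dict  # rbp -> {gene: sign}
    te_targets: dict  # rbp -> {gene: sign}
    clip_targets: dict  # rbp -> set of bound genes (effects may be 0)
    effect_sizes: dict  # rbp -> effect size
    rbp_z: pd.DataFrame | None = None  # latent dose, rbp x sample

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rbp in sorted(self.traits):
            effects = {
                g: ("mRNA", s) for g, s in self.mrna_targets.get(rbp, {}).items()
            }
            for g, s in self.te_targets.get(rbp, {}).items():
                if g in effects:
                    rows.append({
                        "rbp": rbp, "label": self.traits[rbp], "gene": g,
                        "affected_trait": "TE", "sign": s,
                        "effect_size": self.effect_sizes[rbp],
                    })
                else:
                    effects[g] = ("TE", s)
            for g in sorted(self.clip_targets.get(rbp, set())):
                trait, sign = effects.get(g, ("none", 0))
                rows.append({
                    "rbp": rbp, "label": self.traits[rbp], "gene": g,
                    "affected_trait": trait, "sign": sign,
                    "effect_size": self.effect_sizes[rbp] if trait != "none" else 0.0,
                })
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, tab: pd.DataFrame) -> "SimTruth":
        traits, mrna, te, clip, sizes = {}, {}, {}, {}, {}
        for row in tab.itertuples(index=False):
            traits[row.rbp] = row.label
            clip.setdefault(row.rbp, set()).add(row.gene)
            if row.affected_trait == "mRNA":
                mrna.setdefault(row.rbp, {})[row.gene] = int(row.sign)
                sizes[row.rbp] = float(row.effect_size)
            elif row.affected_trait == "TE":
                te.setdefault(row.rbp, {})[row.gene] = int(row.sign)
                sizes[row.rbp] = float(row.effect_size)
            sizes.setdefault(row.rbp, 0.0)
        return cls(traits=traits, mrna_targets=mrna, te_targets=te,
                   clip_targets=clip, effect_sizes=sizes)

    @classmethod
    def load(cls, path) -> "SimTruth":
        # keep_default_na: the "null" trait label is data, not a missing value
        return cls.from_frame(pd.read_csv(path, sep="\t", keep_default_na=False))


# ---------------------------------------------------------------------------
# annotation


def _split_lengths(total: int, parts: int, rng: np.random.Generator, min_len: int = 10):
    """Split ``total`` into ``parts`` chunks of at least ``min_len``."""
    parts = max(1, min(parts, total // min_len))
    if parts == 1:
        return [total]
    cuts = np.sort(rng.choice(total - parts * min_len + 1, size=parts - 1, replace=True))
    sizes = np.diff(np.concatenate([[0], cuts, [total - parts * min_len]]))
    return list(sizes + min_len)


def generate_annotation(
    n_genes: int,
    length_params: dict | None = None,
    seed: int = 0,
    gene_ids: list[str] | None = None,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Generate one multi-exon transcript per gene (GTF convention).

    Region lengths are lognormal; the CDS is rounded up to a multiple of 3.
    The mRNA is laid out 5'UTR / CDS / 3'UTR in transcript order over the
    exon chain, on a random strand; genes are placed sequentially with gaps.
    """
    if n_genes <= 0:
        raise SimulationError("n_genes must be positive")
    params = dict(DEFAULT_LENGTH_PARAMS)
    if length_params:
        params.update(length_params)
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise SimulationError("gene_ids length must equal n_genes")

    rows = []
    cursor = 1  # 1-based
    for gene in gene_ids:
        u5 = max(20, int(np.round(rng.lognormal(*params["utr5"]))))
        cds = max(30, int(np.round(rng.lognormal(*params["cds"]))))
        cds += (-cds) % 3
        u3 = max(20, int(np.round(rng.lognormal(*params["utr3"]))))
        total = u5 + cds + u3
        n_exons = 1 + rng.poisson(max(params["n_exons_mean"] - 1.0, 0.0))
        exon_lengths = _split_lengths(total, n_exons, rng, min_len=30)
        strand = "+" if rng.random() < 0.5 else "-"

        exons = []
        pos = cursor
        for k, el in enumerate(exon_lengths):
            exons.append((pos, pos + el - 1))  # 1-based inclusive
            pos += el
            if k < len(exon_lengths) - 1:
                pos += max(50, int(np.round(rng.lognormal(*params["intron"]))))
        tx_start, tx_end = exons[0][0], exons[-1][1]

        rows.append(dict(chrom=chrom, feature="transcript", start=tx_start,
                         end=tx_end, strand=strand, gene_id=gene,
                         transcript_id=f"T_{gene}"))
        for s, e in exons:
            rows.append(dict(chrom=chrom, feature="exon", start=s, end=e,
                             strand=strand, gene_id=gene,
                             transcript_id=f"T_{gene}"))
        rows.extend(_region_rows(exons, strand, u5, cds, gene, chrom))
        cursor = tx_end + 1 + 1000  # intergenic gap

    return pd.DataFrame(rows)


def _region_rows(exons, strand, u5, cds, gene, chrom):
    """Slice the exon chain (transcript order) into 5'UTR/CDS/3'UTR rows."""
    ordered = exons if strand == "+" else exons[::-1]
    boundaries = [u5, u5 + cds]
    feature_of = ["five_prime_utr", "CDS", "three_prime_utr"]
    rows = []
    t = 0  # transcript coordinate
    for s, e in ordered:
        length = e - s + 1
        seg_start = 0
        while seg_start < length:
            tpos = t + seg_start
            region_idx = sum(tpos >= b for b in boundaries)
            next_b = ([b for b in boundaries if b > tpos] + [t + length])[0]
            seg_len = min(next_b - tpos, length - seg_start)
            if strand == "+":
                gs = s + seg_start
                ge = gs + seg_len - 1
            else:
                ge = e - seg_start
                gs = ge - seg_len + 1
            rows.append(dict(chrom=chrom, feature=feature_of[region_idx],
                             start=gs, end=ge, strand=strand, gene_id=gene,
                             transcript_id=f"T_{gene}"))
            seg_start += seg_len
        t += length
    return rows


# ---------------------------------------------------------------------------
# cohort


def _draw_negbin(rng: np.random.Generator, mu: np.ndarray, dispersion: float):
    if dispersion < 1e-8:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_cohort(config: SimConfig):
    """Simulate matched RNA and Ribo count matrices plus the truth table.

    Returns (rna: CountMatrix, ribo: CountMatrix, truth: SimTruth).  The RBP
    genes appear as extra rows in both matrices (ids from the RBP specs).
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids
    samples = config.sample_ids
    rbp_names = [s.name for s in config.rbps]
    if len(set(rbp_names)) != len(rbp_names):
        raise SimulationError("duplicate RBP names")
    all_genes = genes + rbp_names
    n_s = config.n_samples

    base = rng.normal(config.gene_log_mean, config.gene_log_sd, size=len(genes))
    te_base = rng.normal(0.0, config.te_log_sd, size=len(genes))
    z = rng.normal(size=(len(config.rbps), n_s))

    log_mu = np.tile(base[:, None], (1, n_s))
    log_te = np.tile(te_base[:, None], (1, n_s))

    truth = SimTruth(traits={}, mrna_targets={}, te_targets={},
                     clip_targets={}, effect_sizes={},
                     rbp_z=pd.DataFrame(z, index=rbp_names, columns=samples))
    gene_pos = {g: i for i, g in enumerate(genes)}

    for r, spec in enumerate(config.rbps):
        truth.traits[spec.name] = spec.trait
        truth.effect_sizes[spec.name] = spec.effect_size
        mrna_set, te_set = _draw_target_sets(spec, genes, rng)
        signs_m = _draw_signs(spec, len(mrna_set), rng)
        signs_t = _draw_signs(spec, len(te_set), rng)
        truth.mrna_targets[spec.name] = dict(zip(mrna_set, signs_m))
        truth.te_targets[spec.name] = dict(zip(te_set, signs_t))
        bound = set(mrna_set) | set(te_set)
        if spec.trait == "null":
            bound = set(rng.choice(genes, size=spec.n_targets, replace=False))
        truth.clip_targets[spec.name] = bound
        for g, s in truth.mrna_targets[spec.name].items():
            log_mu[gene_pos[g]] += spec.effect_size * s * z[r]
        for g, s in truth.te_targets[spec.name].items():
            log_te[gene_pos[g]] += spec.effect_size * s * z[r]

    # RBP rows: lognormal across samples, driven by the latent dose
    rbp_base = rng.normal(config.gene_log_mean + 0.5, 0.3, size=len(config.rbps))
    rbp_log_mu = rbp_base[:, None] + config.rbp_log_sd * z

    mu_rna = np.vstack([np.exp(log_mu), np.exp(rbp_log_mu)])
    mu_ribo = mu_rna * np.vstack([np.exp(log_te), np.ones_like(rbp_log_mu)])

    lo, hi = config.library_size_range
    counts = {}
    for assay, mu in (("RNA", mu_rna), ("RIBO", mu_ribo)):
        totals = rng.uniform(lo, hi, size=n_s)
        props = mu / mu.sum(axis=0, keepdims=True)
        lam = props * totals[None, :]
        counts[assay] = _draw_negbin(rng, lam, config.dispersion)

    rna = CountMatrix(
        counts=pd.DataFrame(counts["RNA"], index=all_genes, columns=samples),
        assay="RNA",
    )
    ribo = CountMatrix(
        counts=pd.DataFrame(counts["RIBO"], index=all_genes, columns=samples),
        assay="RIBO",
    )
    return rna, ribo, truth


def _draw_target_sets(spec: RbpSpec, genes: list[str], rng: np.random.Generator):
    if spec.trait == "mRNA":
        return list(rng.choice(genes, size=spec.n_targets, replace=False)), []
    if spec.trait == "TE":
        return [], list(rng.choice(genes, size=spec.n_targets, replace=False))
    if spec.trait == "both":
        n_shared = int(round(spec.overlap_fraction * spec.n_targets))
        pool = rng.choice(genes, size=2 * spec.n_targets - n_shared, replace=False)
        mrna = list(pool[: spec.n_targets])
        te = list(pool[spec.n_targets - n_shared:])
        return mrna, te
    return [], []


def _draw_signs(spec: RbpSpec, n: int, rng: np.random.Generator):
    if spec.effect_sign == "random":
        return list(rng.choice([-1, 1], size=n))
    return [int(spec.effect_sign)] * n


# ---------------------------------------------------------------------------
# CLIP peaks

REGION_WEIGHTS = {"CDS": 0.45, "3UTR": 0.25, "5UTR": 0.15, "intron": 0.15}


def generate_clip_peaks(
    truth: SimTruth,
    models: GeneModels,
    clip_fp_rate: float = 0.02,
    clip_fn_rate: float = 0.1,
    n_replicates: int = 2,
    seed: int = 0,
    ip_total: int = 1_000_000,
    input_total: int = 1_000_000,
) -> pd.DataFrame:
    """BED6+ peak table (0-based half-open) for every RBP in the truth.

    Bound genes receive 1-3 peaks with replicate-correlated IP enrichment;
    each unbound gene receives a decoy peak with probability
    ``clip_fp_rate`` whose IP and input reads are exchangeable and
    independent across replicates.
    """
    if n_replicates < 2:
        raise SimulationError("IDR needs at least 2 replicates")
    for rate in (clip_fp_rate, clip_fn_rate):
        if not (0.0 <= rate <= 1.0):
            raise SimulationError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    all_genes = models.genes()
    rows = []
    for rbp in sorted(truth.traits):
        bound = sorted(truth.clip_targets.get(rbp, set()))
        kept = [g for g in bound if rng.random() >= clip_fn_rate]
        decoys = [
            g for g in all_genes
            if g not in truth.clip_targets.get(rbp, set())
            and rng.random() < clip_fp_rate
        ]
        for gene in kept:
            n_peaks = 1 + int(rng.poisson(0.5))
            for _ in range(n_peaks):
                rows.append(_make_peak(rbp, gene, models, rng, True,
                                       n_replicates, ip_total, input_total))
        for gene in decoys:
            rows.append(_make_peak(rbp, gene, models, rng, False,
                                   n_replicates, ip_total, input_total))
    flat = [r for peak in rows for r in peak]
    df = pd.DataFrame(flat)
    if df.empty:
        df = pd.DataFrame(columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "ip_reads", "input_reads", "ip_total", "input_total",
            "rbp", "replicate", "gene_id",
        ])
    return df.sort_values(["rbp", "chrom", "start", "replicate"]).reset_index(drop=True)


def _make_peak(rbp, gene, models: GeneModels, rng, is_true, n_replicates,
               ip_total, input_total):
    tx = models.by_gene[gene][0]
    interval = _choose_interval(tx, rng)
    width = int(rng.integers(40, 100))
    s, e = interval
    if e - s <= width:
        start, end = s, e
    else:
        start = int(rng.integers(s, e - width))
        end = start + width
    base = rng.uniform(10, 30)
    if is_true:
        fc = float(np.exp(rng.normal(np.log(18.0), 0.6)))
        rep_noise = np.exp(rng.normal(0.0, 0.1, size=n_replicates))
        ip_lam = base * fc * rep_noise
        input_lam = np.full(n_replicates, base)
    else:
        # input-like on average, but with independent per-replicate spurious
        # enrichment so decoy scores interleave with true ones and are
        # rank-discordant across replicates (what IDR is meant to catch)
        spurious = np.exp(rng.normal(0.0, 1.2, size=n_replicates))
        ip_lam = base * spurious
        input_lam = np.full(n_replicates, base)
    out = []
    for rep in range(n_replicates):
        out.append(dict(
            chrom=tx.chrom, start=start, end=end,
            name=f"{rbp}:rep{rep + 1}", score=0, strand=tx.strand,
            ip_reads=int(rng.poisson(ip_lam[rep])),
            input_reads=int(rng.poisson(input_lam[rep])),
            ip_total=ip_total, input_total=input_total,
            rbp=rbp, replicate=f"rep{rep + 1}", gene_id=gene,
        ))
    return out


def _choose_interval(tx, rng):
    candidates = []
    weights = []
    for region, w in REGION_WEIGHTS.items():
        if region == "intron":
            introns = _introns(tx)
            if introns:
                candidates.append(introns)
                weights.append(w)
        elif tx.regions.get(region):
            candidates.append(tx.regions[region])
            weights.append(w)
    weights = np.array(weights) / np.sum(weights)
    pick = rng.choice(len(candidates), p=weights)
    ivs = candidates[pick]
    widths = np.array([e - s for s, e in ivs], dtype=float)
    k = rng.choice(len(ivs), p=widths / widths.sum())
    return ivs[k]


def _introns(tx):
    out = []
    for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
        if s2 > e1:
            out.append((e1, s2))
    return out


# ---------------------------------------------------------------------------
# 5'UTR sequences

_UNSTRUCTURED_PROBS = {"A": 0.55, "C": 0.35, "G": 0.05, "U": 0.05}


def generate_utr_sequences(
    utr_lengths: pd.Series,
    class_map: dict[str, str],
    seed: int = 0,
) -> dict[str, str]:
    """FASTA-ready 5'UTR sequences whose foldability differs by class.

    ``class_map`` assigns each gene "structured" (GC-rich palindromic stems
    with short loops) or "unstructured" (A/C-dominated composition with few
    pairing partners).  Sequence length equals the annotated 5'UTR length.
    """
    rng = np.random.default_rng(seed)
    out = {}
    letters = np.array(list(_UNSTRUCTURED_PROBS))
    probs = np.array(list(_UNSTRUCTURED_PROBS.values()))
    for gene in sorted(class_map):
        cls = class_map[gene]
        length = int(utr_lengths.loc[gene])
        if cls == "unstructured":
            seq = "".join(rng.choice(letters, size=length, p=probs))
        elif cls == "structured":
            seq = _structured_sequence(length, rng)
        else:
            raise SimulationError(f"unknown UTR class {cls!r} for {gene}")
        out[gene] = seq
    return out


def _structured_sequence(length: int, rng: np.random.Generator) -> str:
    comp = {"G": "C", "C": "G", "A": "U", "U": "A"}
    pieces = []
    n = 0
    while n < length:
        stem_len = int(rng.integers(6, 12))
        stem = "".join(rng.choice(["G", "C"], size=stem_len))
        loop = "".join(rng.choice(["A", "U"], size=4))
        rc = "".join(comp[b] for b in reversed(stem))
        spacer = "".join(rng.choice(["A", "C"], size=int(rng.integers(2, 6))))
        unit = stem + loop + rc + spacer
        pieces.append(unit)
        n += len(unit)
    seq = "".join(pieces)[:length]
    if len(seq) < length:
        seq += "A" * (length - len(seq))
    return seq


# ---------------------------------------------------------------------------
# splicing


def generate_splicing(
    truth: SimTruth,
    rbp: str,
    coupling: float,
    seed: int = 0,
    genes: list[str] | None = None,
    psi_noise_sd: float = 0.3,
    mean_coverage: float = 60.0,
    te_offset: float = -0.5,
):
    """Cassette-exon junction counts coupled to an RBP's dose.

    One cassette exon per designated gene (default: the RBP's TE targets).
    On the logit scale, PSI follows 2*coupling*z plus Gaussian noise.
    Returns (junction table, per-isoform TE table); the inclusion isoform
    carries a log TE offset of ``te_offset`` relative to exclusion.
    """
    if not (-1.0 <= coupling <= 1.0):
        raise SimulationError("coupling must lie in [-1, 1]")
    if truth.rbp_z is None or rbp not in truth.rbp_z.index:
        raise SimulationError(f"no latent dose recorded for RBP {rbp!r}")
    if genes is None:
        genes = sorted(truth.te_targets.get(rbp, {}))
    z = truth.rbp_z.loc[rbp].to_numpy()
    samples = list(truth.rbp_z.columns)
    rng = np.random.default_rng(seed)

    all_clip = set().union(*truth.clip_targets.values()) if truth.clip_targets else set()
    rows = []
    te_rows = []
    for gene in genes:
        if gene not in all_clip:
            raise SimulationError(f"designated gene {gene} absent from annotation/truth")
        exon_id = f"{gene}:cassette"
        psi0 = rng.uniform(0.3, 0.7)
        logit0 = np.log(psi0 / (1 - psi0))
        noise = rng.normal(0.0, psi_noise_sd, size=len(samples))
        logit = logit0 + 2.0 * coupling * z + noise
        psi = 1.0 / (1.0 + np.exp(-logit))
        cov = rng.poisson(mean_coverage, size=len(samples))
        ij_up = rng.poisson(cov * psi)
        ij_down = rng.poisson(cov * psi)
        ej = rng.poisson(cov * (1.0 - psi))
        for i, sample in enumerate(samples):
            rows.append(dict(gene_id=gene, exon_id=exon_id, sample=sample,
                             ij_up=int(ij_up[i]), ij_down=int(ij_down[i]),
                             ej=int(ej[i])))
        te_base = float(np.exp(rng.normal(0.0, 0.2)))
        te_noise = np.exp(rng.normal(0.0, 0.15, size=(2, len(samples))))
        for i, sample in enumerate(samples):
            te_rows.append(dict(gene_id=gene, isoform="inclusion", sample=sample,
                                te=te_base * np.exp(te_offset) * te_noise[0, i]))
            te_rows.append(dict(gene_id=gene, isoform="exclusion", sample=sample,
                                te=te_base * te_noise[1, i]))
    junctions = pd.DataFrame(rows)
    isoform_te = pd.DataFrame(te_rows)
    return junctions, isoform_te
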