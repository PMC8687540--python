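"""End-to-end orchestration: simulate a cohort bundle, run the analysis.

``simulate_bundle`` writes every input the analysis consumes (annotation,
count matrices, CLIP peaks, 5'UTR FASTA, junction counts, a replication
cohort and a tissue TPM table) plus the planted truth.  ``run`` executes the
stages — joint normalization and filtering, CLIP target derivation,
RBP-target correlation, empirical enrichment and classification, target
feature characterization, replication — writing one directory of TSV
outputs per stage plus a machine-readable manifest and a per-RBP summary.
``score_recovery`` joins the summary against the truth and reports label
accuracy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .annotation import GeneModels
from .clip import (assign_targets, compute_idr, filter_peaks, peak_enrichment,
                   pool_peaks, score_information_content)
from .correlate import adjust_bh, correlate_rbp_targets, spearman_matrix
from .enrich import (classify_rbps, enrichment_record, sample_null_sets,
                     target_overlap)
from .features import (classify_ubiquity, cluster_correlation_matrix,
                       compare_lengths, compare_mfe_batch,
                       rbp_overlap_dendrogram, utr_mfe_table)
from .quantify import (compute_fpkm, compute_te, estimate_size_factors,
                       filter_expressed, normalize, psi_matrix_from_junctions)
from .replicate import replicate_rbps
from .simulate import (SimConfig, SimTruth, default_panel, generate_annotation,
                       generate_clip_peaks, generate_cohort,
                       generate_splicing, generate_utr_sequences)

logger = logging.getLogger("rbptraits")


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Thresholds and sizes for one analysis run."""

    alpha: float = 0.05
    min_mean_fpkm: float = 1.0
    min_samples: int = 20
    min_pairs: int = 10
    idr_max: float = 0.01
    peak_p_max: float = 1e-5
    fc_min: float = 8.0
    n_null_sets: int = 100_000
    n_perm: int = 10_000
    min_utr_len: int = 20
    subsample_n: int = 50
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise PipelineError("alpha must lie in (0, 1)")
        if self.n_null_sets < 100:
            raise PipelineError("n_null_sets must be >= 100")
        for name in ("min_samples", "min_pairs", "n_perm", "min_utr_len",
                     "subsample_n"):
            if getattr(self, name) < 1:
                raise PipelineError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# simulate


def simulate_bundle(
    out_dir: str | Path,
    sim_config: SimConfig | None = None,
    with_replication: bool = True,
    with_splicing: bool = True,
) -> Path:
    """Write a complete synthetic input bundle under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = sim_config or SimConfig(rbps=default_panel())
    rng = np.random.default_rng(cfg.seed)

    rna, ribo, truth = generate_cohort(cfg)
    all_genes = list(rna.genes)
    ann = generate_annotation(
        len(all_genes), cfg.length_params, seed=int(rng.integers(2**31)),
        gene_ids=all_genes,
    )
    models = GeneModels.from_table(ann)
    peaks = generate_clip_peaks(
        truth, models, cfg.clip_fp_rate, cfg.clip_fn_rate,
        n_replicates=cfg.clip_replicates, seed=int(rng.integers(2**31)),
    )
    # 5'UTR sequences: TE targets of each RBP fold differently by effect sign
    utr_len = models.feature_lengths("5UTR")
    class_map = {g: "unstructured" for g in all_genes}
    for rbp, targets in truth.te_targets.items():
        for g, sign in targets.items():
            class_map[g] = "structured" if sign < 0 else "unstructured"
    seqs = generate_utr_sequences(utr_len, class_map, seed=int(rng.integers(2**31)))

    io.write_gtf(ann, out / "annotation.gtf")
    io.write_counts_tsv(rna.counts, out / "rna_counts.tsv")
    io.write_counts_tsv(ribo.counts, out / "ribo_counts.tsv")
    io.write_bed_peaks(peaks, out / "clip_peaks.bed")
    io.write_fasta(seqs, out / "utr5.fasta")
    truth.save(out / "truth.tsv")
    truth.rbp_z.to_csv(out / "rbp_dose.tsv", sep="\t", float_format="%.6g")

    if with_splicing:
        te_rbps = [r for r, t in truth.traits.items()
                   if t in ("TE", "both") and truth.te_targets.get(r)]
        if te_rbps:
            rbp = sorted(te_rbps)[0]
            junc, iso_te = generate_splicing(
                truth, rbp, coupling=0.8, seed=int(rng.integers(2**31)),
            )
            io.write_junctions_tsv(junc, out / "junctions.tsv")
            iso_te.to_csv(out / "isoform_te.tsv", sep="\t", index=False,
                          float_format="%.6g")
            (out / "splicing_rbp.txt").write_text(rbp + "\n")

    if with_replication:
        # independent samples, same planted regulatory map
        repl_cfg = SimConfig(**{
            **{f.name: getattr(cfg, f.name) for f in fields(SimConfig)},
            "seed": cfg.seed + 104729,
        })
        r_rna, r_ribo, r_truth = generate_cohort(repl_cfg)
        io.write_counts_tsv(r_rna.counts, out / "replication_rna_counts.tsv")
        io.write_counts_tsv(r_ribo.counts, out / "replication_ribo_counts.tsv")

    # GTEx-style tissue TPM table for the RBPs (most ubiquitously expressed)
    tissues = [f"tissue{i + 1:02d}" for i in range(54)]
    rbp_names = sorted(truth.traits)
    tpm = np.exp(rng.normal(np.log(30.0), 0.8, size=(len(rbp_names), 54)))
    narrow = rng.random(len(rbp_names)) < 0.1  # a few tissue-restricted RBPs
    tpm[narrow, 10:] *= 0.01
    io.write_counts_tsv(
        pd.DataFrame(tpm, index=rbp_names, columns=tissues), out / "tissue_tpm.tsv"
    )
    return out


# ---------------------------------------------------------------------------
# run


def run(
    input_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> Path:
    """Execute every analysis stage on a bundle directory."""
    cfg = config or PipelineConfig()
    cfg.validate()
    inp = Path(input_dir)
    out = Path(out_dir)
    for sub in ("targets", "correlations", "enrichment", "features", "replication"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    required = ["annotation.gtf", "rna_counts.tsv", "ribo_counts.tsv",
                "clip_peaks.bed"]
    missing = [f for f in required if not (inp / f).exists()]
    if missing:
        raise PipelineError(f"missing inputs: {missing}")

    ann = io.read_gtf(inp / "annotation.gtf")
    models = GeneModels.from_table(ann)
    rna_counts = io.read_counts_tsv(inp / "rna_counts.tsv")
    ribo_counts = io.read_counts_tsv(inp / "ribo_counts.tsv")
    peaks = io.read_bed_peaks(inp / "clip_peaks.bed")
    rbp_names = sorted(peaks["rbp"].unique())
    if cfg.min_samples > rna_counts.shape[1]:
        raise PipelineError(
            f"min_samples={cfg.min_samples} exceeds cohort size "
            f"{rna_counts.shape[1]}"
        )

    # --- quantification -----------------------------------------------------
    mrna_trait, te_trait, ribo_norm, expressed = quantify_stage(
        rna_counts, ribo_counts, models, cfg
    )
    logger.info("quantification: %d/%d genes pass the expression filter",
                len(expressed), rna_counts.shape[0])

    # --- CLIP targets -------------------------------------------------------
    target_sets, target_log = clip_stage(peaks, models, cfg)
    targets_long = pd.concat(
        [pd.DataFrame({"rbp": r, "gene": sorted(ts.genes)})
         for r, ts in target_sets.items() if ts.genes],
        ignore_index=True,
    ) if target_sets else pd.DataFrame(columns=["rbp", "gene"])
    targets_long.to_csv(out / "targets" / "targets.tsv", sep="\t", index=False)
    nonempty = {r: ts.region_proportions for r, ts in target_sets.items()
                if not ts.region_proportions.empty}
    regions = (pd.concat(nonempty, names=["rbp", "gene_id"]) if nonempty
               else pd.DataFrame())
    regions.to_csv(out / "targets" / "binding_regions.tsv", sep="\t",
                   float_format="%.4g")
    target_log.to_csv(out / "targets" / "peak_filtering_log.tsv", sep="\t",
                      index=False)

    # --- correlations -------------------------------------------------------
    records = []
    for rbp in rbp_names:
        if rbp not in ribo_norm.index:
            logger.warning("RBP %s absent from expression matrix; skipped", rbp)
            continue
        targets = sorted(target_sets[rbp].genes & set(expressed)) if rbp in target_sets else []
        targets = [g for g in targets if g != rbp]
        for trait_name, trait in (("mRNA", mrna_trait), ("TE", te_trait)):
            rec = correlate_rbp_targets(
                rbp, ribo_norm, trait, targets, trait_name,
                alpha=cfg.alpha, min_pairs=cfg.min_pairs,
            )
            records.append(rec)
    records = [r for r in records if not r.empty]
    correlations = pd.concat(records, ignore_index=True) if records else pd.DataFrame(
        columns=["rbp", "gene", "trait", "rho", "n", "p", "p_adj", "significant"]
    )
    correlations.to_csv(out / "correlations" / "correlations.tsv", sep="\t",
                        index=False, float_format="%.6g")

    # --- enrichment ---------------------------------------------------------
    enr_records, class_tab, overlaps = enrichment_stage(
        rbp_names, target_sets, mrna_trait, te_trait, ribo_norm, expressed,
        cfg,
    )
    enr_records.to_csv(out / "enrichment" / "enrichment.tsv", sep="\t",
                       index=False, float_format="%.6g")
    class_tab.to_csv(out / "enrichment" / "classification.tsv", sep="\t",
                     float_format="%.6g")
    overlaps.to_csv(out / "enrichment" / "target_overlap.tsv", sep="\t",
                    index=False, float_format="%.6g")

    # --- features -----------------------------------------------------------
    features_stage(inp, out, correlations, class_tab, target_sets, models, cfg)

    # --- replication --------------------------------------------------------
    replication_stage(inp, out, correlations, models, cfg)

    # --- summary ------------------------------------------------------------
    summary = class_tab.join(
        overlaps.set_index("rbp")["overlap_pct"], how="left"
    )
    summary.to_csv(out / "summary.tsv", sep="\t", float_format="%.6g")
    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "n_genes": int(rna_counts.shape[0]),
        "n_samples": int(rna_counts.shape[1]),
        "n_rbps": len(rbp_names),
        "n_expressed": int(len(expressed)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def quantify_stage(rna_counts, ribo_counts, models, cfg: PipelineConfig):
    joint = pd.concat(
        [rna_counts.add_suffix("|RNA"), ribo_counts.add_suffix("|RIBO")], axis=1
    )
    sf = estimate_size_factors(joint)
    rna_norm = normalize(rna_counts, sf[[f"{c}|RNA" for c in rna_counts.columns]]
                         .set_axis(rna_counts.columns))
    ribo_norm = normalize(ribo_counts, sf[[f"{c}|RIBO" for c in ribo_counts.columns]]
                          .set_axis(ribo_counts.columns))
    lengths = models.feature_lengths("CDS").reindex(rna_counts.index)
    lengths = lengths.fillna(lengths.median()).clip(lower=1)
    fpkm = compute_fpkm(rna_counts, lengths)
    expressed = filter_expressed(
        fpkm, rna_counts, ribo_counts,
        min_mean_fpkm=cfg.min_mean_fpkm, min_samples=cfg.min_samples,
    )
    te = compute_te(ribo_norm.loc[expressed], rna_norm.loc[expressed])
    return rna_norm.loc[expressed], te, ribo_norm, list(expressed)


def clip_stage(peaks: pd.DataFrame, models: GeneModels, cfg: PipelineConfig):
    """Score, IDR-filter, pool and assign CLIP peaks per RBP."""
    target_sets = {}
    log_rows = []
    for rbp, grp in peaks.groupby("rbp", sort=True):
        reps = sorted(grp["replicate"].unique())
        scored = score_replicate_peaks(grp, reps)
        n_before = len(scored)
        kept = filter_peaks(scored, idr_max=cfg.idr_max, p_max=cfg.peak_p_max,
                            fc_min=cfg.fc_min)
        pooled = pool_peaks(kept) if not kept.empty else kept
        pooled = pooled.assign(rbp=rbp)
        ts = assign_targets(pooled, models)
        target_sets[rbp] = ts
        log_rows.append({
            "rbp": rbp, "n_peaks": n_before, "n_after_filter": len(kept),
            "n_after_pool": len(pooled), "n_targets": len(ts.genes),
            "n_skipped_chroms": ts.skipped_chroms,
        })
    return target_sets, pd.DataFrame(log_rows)


def score_replicate_peaks(grp: pd.DataFrame, reps: list) -> pd.DataFrame:
    """Merge replicate peak calls on overlap; score pooled reads and IDR."""
    by_rep = {r: grp[grp["replicate"] == r].reset_index(drop=True) for r in reps}
    base = by_rep[reps[0]].copy()
    # match replicate peaks to the first replicate's intervals by overlap
    matched_scores = {reps[0]: None}
    ip_sum = base["ip_reads"].to_numpy(dtype=float)
    input_sum = base["input_reads"].to_numpy(dtype=float)
    ip_tot = float(base["ip_total"].iloc[0])
    input_tot = float(base["input_total"].iloc[0])
    ic0 = score_information_content(
        base["ip_reads"].to_numpy(), base["input_reads"].to_numpy(),
        ip_tot, input_tot,
    )
    rep_ics = [np.asarray(ic0)]
    for rep in reps[1:]:
        other = by_rep[rep]
        idx = _match_by_overlap(base, other)
        ok = idx >= 0
        ip = np.where(ok, other["ip_reads"].to_numpy(dtype=float)[idx], 0.0)
        inp = np.where(ok, other["input_reads"].to_numpy(dtype=float)[idx], 0.0)
        ip_sum += ip
        input_sum += inp
        ic = score_information_content(ip, inp, ip_tot, input_tot)
        rep_ics.append(np.asarray(ic))
    fc, pval = peak_enrichment(ip_sum, input_sum,
                               ip_tot * len(reps), input_tot * len(reps))
    out = base.copy()
    out["ip_reads"] = ip_sum
    out["input_reads"] = input_sum
    out["information_content"] = score_information_content(
        ip_sum, input_sum, ip_tot * len(reps), input_tot * len(reps)
    )
    out["fold_change"] = fc
    out["enrichment_p"] = pval
    if len(base) >= 20 and np.ptp(rep_ics[0]) > 0 and np.ptp(rep_ics[1]) > 0:
        out["idr"] = compute_idr(rep_ics[0], rep_ics[1])
    else:  # too few peaks to fit the mixture: treat all as irreproducible
        out["idr"] = 1.0
    return out


def _match_by_overlap(base: pd.DataFrame, other: pd.DataFrame) -> np.ndarray:
    """Index into ``other`` of a same-strand overlapping peak per base peak
    (-1 when absent).  Ties resolved by largest overlap."""
    from intervaltree import IntervalTree

    trees: dict = {}
    for i, row in other.iterrows():
        trees.setdefault((row["chrom"], row["strand"]), IntervalTree()).addi(
            row["start"], row["end"], i
        )
    out = np.full(len(base), -1, dtype=int)
    for i, row in base.reset_index(drop=True).iterrows():
        tree = trees.get((row["chrom"], row["strand"]))
        if tree is None:
            continue
        hits = tree.overlap(row["start"], row["end"])
        if not hits:
            continue
        best = max(
            hits,
            key=lambda iv: min(iv.end, row["end"]) - max(iv.begin, row["start"]),
        )
        out[i] = best.data
    return out


def enrichment_stage(rbp_names, target_sets, mrna_trait, te_trait, ribo_norm,
                     expressed, cfg: PipelineConfig):
    rng = np.random.default_rng(cfg.seed + 7)
    records = []
    sig_targets = {}
    for rbp in rbp_names:
        if rbp not in ribo_norm.index or rbp not in target_sets:
            continue
        x = ribo_norm.loc[rbp].to_numpy(dtype=float)
        targets = sorted(target_sets[rbp].genes & set(expressed) - {rbp})
        for trait_name, trait in (("mRNA", mrna_trait), ("TE", te_trait)):
            pvals = spearman_matrix(x, trait, min_pairs=cfg.min_pairs)
            universe_p = pvals["p"]
            target_p = universe_p.loc[[g for g in targets if g in universe_p.index]]
            if len(target_p) == 0:
                continue
            null = sample_null_sets(
                universe_p, set_size=len(target_p), n_sets=cfg.n_null_sets,
                alpha=cfg.alpha, seed=rng, exclude=[rbp],
            )
            rec = enrichment_record(rbp, trait_name, target_p.to_numpy(), null,
                                    alpha=cfg.alpha)
            records.append(rec)
            adj = adjust_bh(target_p.to_numpy())
            sig = set(target_p.index[adj <= cfg.alpha])
            sig_targets[(rbp, trait_name)] = sig
    rec_tab, class_tab = classify_rbps(records, alpha=cfg.alpha)
    # RBPs with no evaluable targets carry no evidence: label "none"
    present = set(class_tab.index) if not class_tab.empty else set()
    absent = [r for r in rbp_names if r not in present and r in ribo_norm.index]
    if absent:
        filler = pd.DataFrame({
            "mrna_p_adj": np.nan, "te_p_adj": np.nan,
            "mrna_significant": False, "te_significant": False,
            "label": "none",
        }, index=pd.Index(absent, name="rbp"))
        class_tab = pd.concat([class_tab, filler]).sort_index()
    overlap_rows = []
    for rbp in class_tab.index:
        venn, pct = target_overlap(
            sig_targets.get((rbp, "mRNA"), set()),
            sig_targets.get((rbp, "TE"), set()),
        )
        overlap_rows.append({
            "rbp": rbp, "mrna_only": venn[0], "shared": venn[1],
            "te_only": venn[2], "overlap_pct": pct,
        })
    return rec_tab, class_tab, pd.DataFrame(overlap_rows)


def features_stage(inp: Path, out: Path, correlations: pd.DataFrame,
                   class_tab: pd.DataFrame, target_sets, models: GeneModels,
                   cfg: PipelineConfig):
    feat = out / "features"
    if correlations.empty:
        return
    sig = correlations[correlations["significant"]]

    # correlation-profile clustering of TE-RBPs over significant TE targets
    te_sig = sig[sig["trait"] == "TE"]
    if te_sig["rbp"].nunique() >= 2:
        rho_mat = te_sig.pivot_table(index="rbp", columns="gene", values="rho")
        cl = cluster_correlation_matrix(rho_mat)
        pd.DataFrame(cl.linkage,
                     columns=["left", "right", "height", "size"]).to_csv(
            feat / "te_correlation_linkage.tsv", sep="\t", index=False,
            float_format="%.6g")
        cl.flat_labels(min(6, len(cl.labels))).to_csv(
            feat / "te_correlation_clusters.tsv", sep="\t")
        sets = {r: set(g["gene"]) for r, g in te_sig.groupby("rbp")}
        if sum(bool(s) for s in sets.values()) >= 2:
            dend = rbp_overlap_dendrogram(sets)
            pd.DataFrame(dend.linkage,
                         columns=["left", "right", "height", "size"]).to_csv(
                feat / "rbp_overlap_linkage.tsv", sep="\t", index=False,
                float_format="%.6g")

    # CDS-length comparison between mRNA and TE significant target sets
    lengths = models.feature_lengths("CDS")
    rows = []
    for rbp in class_tab.index:
        a = sig[(sig["rbp"] == rbp) & (sig["trait"] == "mRNA")]["gene"]
        b = sig[(sig["rbp"] == rbp) & (sig["trait"] == "TE")]["gene"]
        if len(a) >= 3 and len(b) >= 3:
            w, p = compare_lengths(lengths.loc[a].to_numpy(),
                                   lengths.loc[b].to_numpy())
            rows.append({"rbp": rbp, "feature": "CDS", "W": w, "p": p,
                         "median_mrna": float(lengths.loc[a].median()),
                         "median_te": float(lengths.loc[b].median())})
    len_tab = pd.DataFrame(rows)
    if not len_tab.empty:
        len_tab["p_adj"] = adjust_bh(len_tab["p"].to_numpy())
    len_tab.to_csv(feat / "target_lengths.tsv", sep="\t", index=False,
                   float_format="%.6g")

    # 5'UTR MFE by correlation sign for TE targets
    fasta = inp / "utr5.fasta"
    if fasta.exists():
        seqs = io.read_fasta(fasta)
        used = set(te_sig["gene"])
        mfe_tab = utr_mfe_table({g: s for g, s in seqs.items() if g in used},
                                min_length=cfg.min_utr_len)
        mfe_tab.to_csv(feat / "utr5_mfe.tsv", sep="\t", float_format="%.6g")
        groups = {}
        for rbp, grp in te_sig.groupby("rbp"):
            pos = set(grp[grp["rho"] > 0]["gene"])
            neg = set(grp[grp["rho"] < 0]["gene"])
            groups[rbp] = (pos, neg)
        comp = compare_mfe_batch(mfe_tab, groups)
        comp.to_csv(feat / "utr5_mfe_by_sign.tsv", sep="\t", index=False,
                    float_format="%.6g")

    # PSI coupling for the designated splicing RBP
    junc_path = inp / "junctions.tsv"
    rbp_file = inp / "splicing_rbp.txt"
    if junc_path.exists() and rbp_file.exists():
        junctions = io.read_junctions_tsv(junc_path)
        psi = psi_matrix_from_junctions(junctions)
        psi.to_csv(feat / "psi_matrix.tsv", sep="\t", float_format="%.4g")

    # ubiquity classification from a tissue TPM table
    tpm_path = inp / "tissue_tpm.tsv"
    if tpm_path.exists():
        tpm = io.read_counts_tsv(tpm_path)
        classify_ubiquity(tpm).to_csv(feat / "ubiquity.tsv", sep="\t")


def replication_stage(inp: Path, out: Path, correlations: pd.DataFrame,
                      models: GeneModels, cfg: PipelineConfig):
    r_rna_path = inp / "replication_rna_counts.tsv"
    r_ribo_path = inp / "replication_ribo_counts.tsv"
    if not (r_rna_path.exists() and r_ribo_path.exists()) or correlations.empty:
        return
    r_rna = io.read_counts_tsv(r_rna_path)
    r_ribo = io.read_counts_tsv(r_ribo_path)
    min_samples = min(cfg.min_samples, r_rna.shape[1])
    repl_cfg = PipelineConfig(**{**asdict(cfg), "min_samples": min_samples})
    mrna_trait, te_trait, ribo_norm, _ = quantify_stage(
        r_rna, r_ribo, models, repl_cfg
    )
    # correlation table of the replication cohort for the discovery pairs
    disc = correlations[correlations["significant"]]
    rows = []
    for (rbp, trait_name), grp in disc.groupby(["rbp", "trait"]):
        if rbp not in ribo_norm.index:
            continue
        trait = mrna_trait if trait_name == "mRNA" else te_trait
        genes = [g for g in grp["gene"] if g in trait.index]
        if not genes:
            continue
        res = spearman_matrix(ribo_norm.loc[rbp].to_numpy(dtype=float),
                              trait.loc[genes], min_pairs=cfg.min_pairs)
        for g in genes:
            rows.append({"rbp": rbp, "gene": g, "trait": trait_name,
                         "rho": res.loc[g, "rho"]})
    repl_table = pd.DataFrame(rows)
    if repl_table.empty:
        return
    result = replicate_rbps(correlations, repl_table, n_perm=cfg.n_perm,
                            seed=cfg.seed + 13)
    result.to_csv(out / "replication" / "replication.tsv", sep="\t",
                  index=False, float_format="%.6g")
    repl_table.to_csv(out / "replication" / "replication_correlations.tsv",
                      sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# recovery scoring

_LABEL_OF_TRAIT = {"mRNA": "mRNA-RBP", "TE": "TE-RBP", "both": "multifunctional",
                   "null": "none"}


def score_recovery(truth: SimTruth | str | Path, summary: pd.DataFrame | str | Path) -> dict:
    """Compare recovered per-RBP labels against the planted truth."""
    if not isinstance(truth, SimTruth):
        truth = SimTruth.load(truth)
    if not isinstance(summary, pd.DataFrame):
        summary = pd.read_csv(summary, sep="\t", index_col=0)
    rows = []
    for rbp, planted in sorted(truth.traits.items()):
        expected = _LABEL_OF_TRAIT[planted]
        got = summary.loc[rbp, "label"] if rbp in summary.index else "missing"
        rows.append({"rbp": rbp, "planted": expected, "recovered": got,
                     "correct": got == expected})
    tab = pd.DataFrame(rows)
    dual = tab[tab["planted"] == "multifunctional"]["rbp"]
    overlaps = []
    for rbp in dual:
        if rbp in summary.index and "overlap_pct" in summary.columns:
            v = summary.loc[rbp, "overlap_pct"]
            if pd.notna(v):
                overlaps.append(float(v))
    per_class = {
        cls: float(grp["correct"].mean())
        for cls, grp in tab.groupby("planted")
    }
    return {
        "n_rbps": len(tab),
        "accuracy": float(tab["correct"].mean()),
        "per_class_accuracy": per_class,
        "dual_overlap_pct_mean": float(np.mean(overlaps)) if overlaps else None,
        "dual_overlap_pct_max": float(np.max(overlaps)) if overlaps else None,
        "table": tab,
    }
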