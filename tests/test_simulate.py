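import numpy as np
import pandas as pd
import pytest

from rbptraits.annotation import GeneModels
from rbptraits.clip import assign_targets
from rbptraits.correlate import spearman, spearman_matrix
from rbptraits.quantify import compute_te, estimate_size_factors, normalize
from rbptraits.simulate import (RbpSpec, SimConfig, SimulationError,
                                default_panel, generate_annotation,
                                generate_clip_peaks, generate_cohort,
                                generate_splicing, generate_utr_sequences)

FIXED_LENGTHS = {
    "utr5": (np.log(100.0), 0.0),
    "cds": (np.log(300.0), 0.0),
    "utr3": (np.log(200.0), 0.0),
    "n_exons_mean": 1.0,
}


def te_matrix(rna, ribo):
    joint = pd.concat([rna.counts.add_suffix("|RNA"),
                       ribo.counts.add_suffix("|RIBO")], axis=1)
    sf = estimate_size_factors(joint)
    rna_n = normalize(rna.counts, sf[[f"{c}|RNA" for c in rna.counts.columns]]
                      .set_axis(rna.counts.columns))
    ribo_n = normalize(ribo.counts, sf[[f"{c}|RIBO" for c in ribo.counts.columns]]
                       .set_axis(ribo.counts.columns))
    return rna_n, ribo_n, compute_te(ribo_n, rna_n)


class TestAnnotation:
    def test_single_gene_fixed_lengths(self):
        ann = generate_annotation(1, FIXED_LENGTHS, seed=0)
        exons = ann[ann["feature"] == "exon"]
        assert (exons["end"] - exons["start"] + 1).sum() == 600
        cds = ann[ann["feature"] == "CDS"]
        assert (cds["end"] - cds["start"] + 1).sum() == 300

    def test_cds_length_divisible_by_three(self):
        ann = generate_annotation(50, seed=1)
        cds_len = (ann[ann["feature"] == "CDS"]
                   .assign(length=lambda d: d["end"] - d["start"] + 1)
                   .groupby("gene_id")["length"].sum())
        assert (cds_len % 3 == 0).all()

    def test_regions_partition_the_exons(self):
        ann = generate_annotation(30, seed=2)
        exon_len = (ann[ann["feature"] == "exon"]
                    .assign(length=lambda d: d["end"] - d["start"] + 1)
                    .groupby("gene_id")["length"].sum())
        region_len = (ann[ann["feature"].isin(
            ["five_prime_utr", "CDS", "three_prime_utr"])]
            .assign(length=lambda d: d["end"] - d["start"] + 1)
            .groupby("gene_id")["length"].sum())
        pd.testing.assert_series_equal(exon_len, region_len, check_names=False)

    def test_same_seed_is_byte_identical(self, tmp_path):
        from rbptraits.io import write_gtf
        a = generate_annotation(20, seed=3)
        b = generate_annotation(20, seed=3)
        pd.testing.assert_frame_equal(a, b)
        write_gtf(a, tmp_path / "a.gtf")
        write_gtf(b, tmp_path / "b.gtf")
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_median_cds_length_tracks_the_sampling_distribution(self):
        ann = generate_annotation(2000, {"cds": (np.log(1500.0), 0.7)}, seed=4)
        cds_len = (ann[ann["feature"] == "CDS"]
                   .assign(length=lambda d: d["end"] - d["start"] + 1)
                   .groupby("gene_id")["length"].sum())
        assert abs(cds_len.median() - 1500) / 1500 < 0.10

    def test_nonpositive_n_genes_rejected(self):
        with pytest.raises(SimulationError):
            generate_annotation(0)


class TestCohort:
    def test_matrices_share_genes_and_samples(self, small_cohort):
        cfg, rna, ribo, truth = small_cohort
        assert list(rna.genes) == list(ribo.genes)
        assert list(rna.samples) == list(ribo.samples)
        for rbp in truth.traits:
            assert rbp in rna.counts.index

    def test_same_config_reproduces_counts(self):
        cfg = SimConfig(n_genes=100, n_samples=10,
                        rbps=(RbpSpec("R1", "TE", n_targets=10),), seed=5)
        a = generate_cohort(cfg)[0]
        b = generate_cohort(cfg)[0]
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_zero_effect_sizes_give_null_correlations(self):
        rbps = tuple(RbpSpec(f"R{i}", "TE", n_targets=100, effect_size=0.0)
                     for i in range(5))
        cfg = SimConfig(n_genes=600, n_samples=80, rbps=rbps, seed=6)
        rna, ribo, truth = generate_cohort(cfg)
        _, ribo_n, te = te_matrix(rna, ribo)
        rhos = []
        for rbp in truth.traits:
            targets = sorted(truth.te_targets[rbp])
            res = spearman_matrix(ribo_n.loc[rbp].to_numpy(), te.loc[targets])
            rhos.extend(res["rho"].dropna().tolist())
        assert len(rhos) == 500
        assert abs(np.mean(rhos)) < 2 / np.sqrt(500 * cfg.n_samples)

    def test_noise_free_limit_recovers_perfect_correlation(self):
        rbps = (RbpSpec("R1", "TE", n_targets=20, effect_size=2.5,
                        effect_sign=1),)
        cfg = SimConfig(n_genes=200, n_samples=60, rbps=rbps,
                        dispersion=1e-9, gene_log_mean=np.log(3000.0), seed=7)
        rna, ribo, truth = generate_cohort(cfg)
        _, ribo_n, te = te_matrix(rna, ribo)
        targets = sorted(truth.te_targets["R1"])
        res = spearman_matrix(ribo_n.loc["R1"].to_numpy(), te.loc[targets])
        assert res["rho"].min() > 0.95

    def test_unit_effect_yields_strong_te_correlations(self):
        rbps = (RbpSpec("R1", "TE", n_targets=100, effect_size=1.0),)
        cfg = SimConfig(n_genes=1000, n_samples=80, rbps=rbps,
                        dispersion=0.1, seed=8)
        rna, ribo, truth = generate_cohort(cfg)
        _, ribo_n, te = te_matrix(rna, ribo)
        targets = sorted(truth.te_targets["R1"])
        res = spearman_matrix(ribo_n.loc["R1"].to_numpy(), te.loc[targets])
        assert res["rho"].abs().mean() >= 0.4

    def test_counts_match_negative_binomial_moments(self):
        cfg = SimConfig(n_genes=500, n_samples=80, rbps=(), dispersion=0.1,
                        seed=9)
        rna, _, _ = generate_cohort(cfg)
        counts = rna.counts.to_numpy(dtype=float)
        mean = counts.mean(axis=1)
        var = counts.var(axis=1, ddof=1)
        expected = mean + cfg.dispersion * mean**2
        ratio = np.median(var / expected)
        assert 0.8 < ratio < 1.2

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(n_genes=10, n_samples=5, dispersion=0.0)

    def test_oversized_target_set_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(n_genes=10, n_samples=5,
                      rbps=(RbpSpec("R", "TE", n_targets=11),))

    def test_dual_trait_overlap_fraction_is_honored(self):
        spec = RbpSpec("R", "both", n_targets=50, overlap_fraction=0.4)
        cfg = SimConfig(n_genes=500, n_samples=10, rbps=(spec,), seed=10)
        _, _, truth = generate_cohort(cfg)
        shared = set(truth.mrna_targets["R"]) & set(truth.te_targets["R"])
        assert len(shared) == 20
        assert len(truth.mrna_targets["R"]) == 50
        assert len(truth.te_targets["R"]) == 50


class TestClipPeaks:
    def test_perfect_rates_recover_truth_exactly(self, small_cohort):
        cfg, rna, ribo, truth = small_cohort
        ann = generate_annotation(len(rna.genes), seed=12,
                                  gene_ids=list(rna.genes))
        models = GeneModels.from_table(ann)
        peaks = generate_clip_peaks(truth, models, 0.0, 0.0, seed=13)
        for rbp in truth.traits:
            sub = peaks[(peaks["rbp"] == rbp) & (peaks["replicate"] == "rep1")]
            ts = assign_targets(sub, models)
            assert ts.genes == truth.clip_targets[rbp]

    def test_total_false_negatives_empty_the_target_sets(self, small_cohort):
        cfg, rna, ribo, truth = small_cohort
        ann = generate_annotation(len(rna.genes), seed=12,
                                  gene_ids=list(rna.genes))
        models = GeneModels.from_table(ann)
        peaks = generate_clip_peaks(truth, models, 0.0, 1.0, seed=14)
        assert peaks.empty

    def test_decoy_count_is_binomial(self):
        truth_rbps = (RbpSpec("R", "null", n_targets=0),)
        cfg = SimConfig(n_genes=1000, n_samples=5, rbps=truth_rbps, seed=15)
        _, _, truth = generate_cohort(cfg)
        ann = generate_annotation(1000, seed=16, gene_ids=cfg.gene_ids)
        models = GeneModels.from_table(ann)
        peaks = generate_clip_peaks(truth, models, 0.2, 0.0, seed=17)
        n_decoy = peaks[peaks["replicate"] == "rep1"]["gene_id"].nunique()
        sd = np.sqrt(1000 * 0.2 * 0.8)
        assert abs(n_decoy - 200) <= 3 * sd

    def test_single_replicate_rejected(self, small_cohort):
        cfg, rna, ribo, truth = small_cohort
        with pytest.raises(SimulationError):
            generate_clip_peaks(truth, None, 0.0, 0.0, n_replicates=1)


class TestUtrSequences:
    def test_lengths_and_alphabet(self):
        lengths = pd.Series([30, 45], index=["g1", "g2"])
        seqs = generate_utr_sequences(
            lengths, {"g1": "structured", "g2": "unstructured"}, seed=18)
        assert len(seqs["g1"]) == 30 and len(seqs["g2"]) == 45
        assert set("".join(seqs.values())) <= set("ACGU")

    def test_same_seed_gives_identical_fasta_bytes(self, tmp_path):
        from rbptraits.io import write_fasta
        lengths = pd.Series([30] * 5, index=[f"g{i}" for i in range(5)])
        classes = {g: "structured" for g in lengths.index}
        for name in ("a", "b"):
            write_fasta(generate_utr_sequences(lengths, classes, seed=19),
                        tmp_path / f"{name}.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_unknown_class_rejected(self):
        with pytest.raises(SimulationError):
            generate_utr_sequences(pd.Series([30], index=["g"]),
                                   {"g": "wobbly"}, seed=0)


class TestSplicing:
    def _truth(self, coupling_seed=20, n_samples=80):
        rbps = (RbpSpec("R1", "TE", n_targets=20),)
        cfg = SimConfig(n_genes=200, n_samples=n_samples, rbps=rbps,
                        seed=coupling_seed)
        return generate_cohort(cfg)[2]

    def test_zero_coupling_centers_psi_correlation_at_zero(self):
        truth = self._truth()
        junc, _ = generate_splicing(truth, "R1", coupling=0.0, seed=21)
        z = truth.rbp_z.loc["R1"]
        rhos = []
        for exon, grp in junc.groupby("exon_id"):
            grp = grp.set_index("sample").loc[z.index]
            psi = (grp["ij_up"] + grp["ij_down"]) / 2
            psi = psi / (psi + grp["ej"])
            rhos.append(spearman(z.to_numpy(), psi.to_numpy())[0])
        assert abs(np.mean(rhos)) < 0.15

    def test_full_negative_coupling_without_noise_is_monotone(self):
        truth = self._truth()
        junc, _ = generate_splicing(truth, "R1", coupling=-1.0, seed=22,
                                    psi_noise_sd=0.0, mean_coverage=5000)
        z = truth.rbp_z.loc["R1"]
        order = np.argsort(z.to_numpy())
        gene = junc["gene_id"].iloc[0]
        grp = junc[junc["gene_id"] == gene].set_index("sample").loc[z.index]
        psi = ((grp["ij_up"] + grp["ij_down"]) / 2
               / ((grp["ij_up"] + grp["ij_down"]) / 2 + grp["ej"]))
        rho = spearman(z.to_numpy(), psi.to_numpy())[0]
        assert rho < -0.99

    def test_strong_coupling_recovers_high_psi_correlations(self):
        truth = self._truth()
        junc, _ = generate_splicing(truth, "R1", coupling=0.8, seed=23)
        z = truth.rbp_z.loc["R1"]
        good = 0
        exons = junc["exon_id"].unique()
        for exon in exons:
            grp = junc[junc["exon_id"] == exon].set_index("sample").loc[z.index]
            psi = (grp["ij_up"] + grp["ij_down"]) / 2
            psi = psi / (psi + grp["ej"])
            if spearman(z.to_numpy(), psi.to_numpy())[0] >= 0.6:
                good += 1
        assert good / len(exons) >= 0.9

    def test_isoform_te_offset_direction(self):
        truth = self._truth()
        _, iso = generate_splicing(truth, "R1", coupling=0.5, seed=24,
                                   te_offset=-0.5)
        mean_te = iso.groupby("isoform")["te"].mean()
        assert mean_te["inclusion"] < mean_te["exclusion"]

    def test_unknown_gene_rejected(self):
        truth = self._truth()
        with pytest.raises(SimulationError):
            generate_splicing(truth, "R1", coupling=0.5, seed=25,
                              genes=["NOT_A_GENE"])
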