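from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rbptraits.features import (FeatureError, classify_ubiquity,
                                cluster_correlation_matrix, compare_lengths,
                                compare_mfe_batch, compare_mfe_by_sign,
                                isoform_te_compare, jaccard_distance,
                                length_matched_subsample,
                                rbp_overlap_dendrogram, rank_sum_test,
                                select_principal_isoform, utr_mfe_table)
from rbptraits.simulate import generate_utr_sequences


class TestCorrelationClustering:
    def test_identical_rows_merge_first_at_zero_height(self):
        rho = pd.DataFrame([[0.5, -0.2, 0.1],
                            [0.5, -0.2, 0.1],
                            [-0.9, 0.8, 0.3]], index=["a", "b", "c"])
        cl = cluster_correlation_matrix(rho)
        assert cl.linkage[0, 2] == 0.0
        assert set(cl.linkage[0, :2]) == {0.0, 1.0}

    def test_sign_flip_is_maximally_distant(self):
        row = np.array([0.6, -0.4, 0.8])
        rho = pd.DataFrame([row, -row, 0 * row], index=["a", "b", "z"])
        from scipy.spatial.distance import pdist
        d = pdist(rho.to_numpy())
        # distance(a, -a) = 2|a| is the largest among {a, -a, 0}
        assert d[0] == max(d)

    def test_four_point_worked_example_matches_hand_agglomeration(self):
        # 1-D rows at 0, 1, 5, 7 with complete linkage:
        # (0,1)@1, (5,7)@2, then max-distance join @7
        rho = pd.DataFrame([[0.0], [1.0], [5.0], [7.0]])
        cl = cluster_correlation_matrix(rho, method="complete")
        heights = sorted(cl.linkage[:, 2])
        assert heights == pytest.approx([1.0, 2.0, 7.0])

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(0)
        rho = pd.DataFrame(rng.normal(size=(12, 6)))
        cl = cluster_correlation_matrix(rho)
        h = cl.linkage[:, 2]
        assert (np.diff(h) >= -1e-12).all()

    def test_missing_rho_is_imputed_as_zero(self):
        rho = pd.DataFrame([[0.5, np.nan], [0.5, 0.0], [0.0, 0.9]])
        cl = cluster_correlation_matrix(rho)
        assert cl.linkage[0, 2] == 0.0  # rows 0 and 1 identical after fill

    def test_single_row_rejected(self):
        with pytest.raises(FeatureError):
            cluster_correlation_matrix(pd.DataFrame([[1.0]]))


class TestOverlapDendrogram:
    def test_jaccard_worked_examples(self):
        assert jaccard_distance({"A", "B", "C"}, {"C", "D"}) == 0.75
        assert jaccard_distance({"A"}, {"A"}) == 0.0
        assert jaccard_distance({"A"}, {"B"}) == 1.0

    def test_identical_sets_merge_at_zero(self):
        cl = rbp_overlap_dendrogram({"r1": {"A", "B"}, "r2": {"A", "B"},
                                     "r3": {"X"}})
        assert cl.linkage[0, 2] == 0.0

    def test_all_empty_rejected(self):
        with pytest.raises(FeatureError):
            rbp_overlap_dendrogram({"r1": set(), "r2": set()})


class TestPrincipalIsoform:
    def _lengths(self):
        return pd.DataFrame({
            "gene_id": ["g1", "g1", "g2"],
            "transcript_id": ["t1a", "t1b", "t2"],
            "length": [900, 600, 500],
        })

    def test_highest_expression_wins(self):
        expr = pd.Series({"t1a": 5.0, "t1b": 10.0, "t2": 1.0})
        out = select_principal_isoform(self._lengths(), expr)
        assert out["g1"] == "t1b"

    def test_tie_goes_to_longer_transcript(self):
        expr = pd.Series({"t1a": 5.0, "t1b": 5.0, "t2": 1.0})
        out = select_principal_isoform(self._lengths(), expr)
        assert out["g1"] == "t1a"

    def test_single_isoform_returns_itself(self):
        expr = pd.Series({"t2": 0.5})
        out = select_principal_isoform(self._lengths(), expr)
        assert out["g2"] == "t2"

    def test_no_transcripts_rejected(self):
        with pytest.raises(FeatureError):
            select_principal_isoform(
                pd.DataFrame(columns=["gene_id", "transcript_id", "length"]),
                pd.Series(dtype=float))


class TestRankSum:
    def test_identical_groups_give_p_one(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_exact_separated_groups_worked_example(self):
        # fully separated 3 vs 3: two-sided exact p = 2/C(6,3) = 0.1
        _, p = compare_lengths([1, 2, 3], [10, 20, 30])
        assert p == pytest.approx(0.1)

    def test_statistic_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=10), rng.normal(size=12) + 0.5
        w1, p1 = rank_sum_test(a, b)
        w2, p2 = rank_sum_test(np.exp(a), np.exp(b))
        assert w1 == w2 and p1 == pytest.approx(p2)

    def test_exact_p_matches_full_enumeration_of_arrangements(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n, m = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            pool = rng.permutation(np.arange(1.0, n + m + 1))  # tie-free
            a, b = pool[:n], pool[n:]
            u_obs, p = rank_sum_test(a, b)
            # enumerate all C(n+m, n) assignments of ranks to group a
            ranks = stats.rankdata(np.concatenate([a, b]))
            total, extreme = 0, 0
            mean_u = n * m / 2
            for idx in combinations(range(n + m), n):
                u = sum(ranks[list(idx)]) - n * (n + 1) / 2
                if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
                    extreme += 1
                total += 1
            assert p == pytest.approx(extreme / total, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(FeatureError):
            rank_sum_test([], [1.0])

    def test_small_groups_rejected_for_length_comparison(self):
        with pytest.raises(FeatureError):
            compare_lengths([1, 2], [3, 4, 5])


class TestIsoformTe:
    def test_identical_vectors_give_p_one(self):
        _, p = isoform_te_compare([1.0, 2, 3], [1.0, 2, 3])
        assert p == 1.0

    def test_separated_vectors_exact_p(self):
        _, p = isoform_te_compare([1, 2, 3], [10, 20, 30])
        assert p == pytest.approx(0.1)

    def test_te_offset_recovered_from_simulated_isoforms(self):
        rng = np.random.default_rng(3)
        n = 40
        base = np.exp(rng.normal(0, 0.15, n))
        high = base * np.exp(0.5) * np.exp(rng.normal(0, 0.15, n))
        _, p = isoform_te_compare(high, base)
        assert p < 0.05

    def test_too_few_samples_rejected(self):
        with pytest.raises(FeatureError):
            isoform_te_compare([1.0, 2.0], [1.0, 2.0, 3.0])


class TestMfeComparison:
    def test_structured_class_folds_lower_than_unstructured(self):
        lengths = pd.Series(60, index=[f"g{i}" for i in range(100)])
        classes = {g: ("structured" if i < 50 else "unstructured")
                   for i, g in enumerate(lengths.index)}
        seqs = generate_utr_sequences(lengths, classes, seed=4)
        tab = utr_mfe_table(seqs)
        structured = tab.loc[[g for g in tab.index if classes[g] == "structured"]]
        unstructured = tab.loc[[g for g in tab.index if classes[g] == "unstructured"]]
        assert structured["normalized_mfe"].mean() < unstructured["normalized_mfe"].mean()
        w, p, n_pos, n_neg = compare_mfe_by_sign(
            tab, structured.index, unstructured.index)
        assert p < 0.05 and n_pos == 50 and n_neg == 50

    def test_short_sequences_are_excluded_from_comparisons(self):
        seqs = {"short": "GGGAAAACCC", "long1": "GGGAAAACCC" * 4,
                "long2": "A" * 40, "long3": "A" * 40, "long4": "A" * 40,
                "long5": "GCGCAAAAGCGC" * 3, "long6": "A" * 40}
        tab = utr_mfe_table(seqs, min_length=20)
        assert not tab.loc["short", "evaluable"]
        _, _, n_pos, n_neg = compare_mfe_by_sign(
            tab, {"short", "long1", "long5", "long2"}, {"long3", "long4", "long6"})
        assert n_pos == 3  # "short" dropped

    def test_batched_comparison_applies_bh(self):
        lengths = pd.Series(50, index=[f"g{i}" for i in range(40)])
        classes = {g: ("structured" if i < 20 else "unstructured")
                   for i, g in enumerate(lengths.index)}
        seqs = generate_utr_sequences(lengths, classes, seed=5)
        tab = utr_mfe_table(seqs)
        pos = {g for g in lengths.index if classes[g] == "structured"}
        neg = set(lengths.index) - pos
        out = compare_mfe_batch(tab, {"R1": (pos, neg), "R2": (pos, neg)})
        assert (out["p_adj"] >= out["p"] - 1e-15).all()


class TestLengthMatchedSubsample:
    def test_identical_length_groups_pass_immediately(self):
        rng = np.random.default_rng(6)
        lengths = pd.Series(rng.integers(20, 300, 80).astype(float))
        groups = {"a": lengths.copy(), "b": lengths.copy()}
        groups["b"].index = [f"b{i}" for i in range(80)]
        out = length_matched_subsample(groups, n_per_group=50, seed=1)
        assert len(out["a"]) == 50 and len(out["b"]) == 50

    def test_same_seed_reproduces_subsample(self):
        rng = np.random.default_rng(7)
        groups = {
            "a": pd.Series(rng.integers(20, 300, 100).astype(float),
                           index=[f"a{i}" for i in range(100)]),
            "b": pd.Series(rng.integers(20, 300, 100).astype(float),
                           index=[f"b{i}" for i in range(100)]),
        }
        s1 = length_matched_subsample(groups, n_per_group=50, seed=9)
        s2 = length_matched_subsample(groups, n_per_group=50, seed=9)
        assert s1 == s2

    def test_confounded_groups_are_balanced_after_subsampling(self):
        rng = np.random.default_rng(8)
        groups = {
            "short": pd.Series(rng.gamma(4, 20, 150) + 20,
                               index=[f"s{i}" for i in range(150)]),
            "long": pd.Series(rng.gamma(4, 35, 150) + 40,
                              index=[f"l{i}" for i in range(150)]),
        }
        _, p_before = rank_sum_test(groups["short"], groups["long"])
        assert p_before < 0.01  # strongly confounded to begin with
        out = length_matched_subsample(groups, n_per_group=50, seed=2)
        _, p_after = rank_sum_test(groups["short"].loc[out["short"]],
                                   groups["long"].loc[out["long"]])
        assert p_after > 0.1

    def test_undersized_group_rejected(self):
        groups = {"a": pd.Series([1.0, 2.0]), "b": pd.Series([3.0, 4.0])}
        with pytest.raises(FeatureError):
            length_matched_subsample(groups, n_per_group=50)


class TestUbiquity:
    def _tpm(self, n_high):
        vals = [20.0] * n_high + [0.5] * (54 - n_high)
        return pd.DataFrame([vals], index=["RBP"],
                            columns=[f"t{i}" for i in range(54)])

    def test_31_high_tissues_is_ubiquitous(self):
        assert classify_ubiquity(self._tpm(31)).loc["RBP", "ubiquitous"]

    def test_exactly_30_is_not(self):
        assert not classify_ubiquity(self._tpm(30)).loc["RBP", "ubiquitous"]

    def test_all_zero_row_is_not(self):
        tpm = self._tpm(0) * 0.0
        out = classify_ubiquity(tpm)
        assert not out.loc["RBP", "ubiquitous"]
        assert out.loc["RBP", "n_tissues_detected"] == 0

    def test_no_tissue_columns_rejected(self):
        with pytest.raises(FeatureError):
            classify_ubiquity(pd.DataFrame(index=["RBP"]))
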