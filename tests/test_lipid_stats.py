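import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaprog.lipid_stats import (
    corr_distance,
    estimate_pi0,
    estimate_qvalues,
    fold_difference,
    homa_ir,
    profile_heatmap,
    ratio_heatmap_matrix,
    ward_cluster,
    wilcoxon_per_lipid,
)


def enumeration_wilcoxon(a, b):
    """Oracle: exact two-sided p by enumerating all group labelings."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    na = len(a)
    observed = ranks[:na].sum()
    stats = [
        sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(pooled)), na)
    ]
    mean = np.mean(stats)
    extreme = sum(abs(s - mean) >= abs(observed - mean) - 1e-12 for s in stats)
    return extreme / len(stats)


class TestWilcoxon:
    def test_textbook_exact_case(self):
        assert wilcoxon_per_lipid([1, 2], [3, 4]) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("na,nb,seed", [(3, 3, 0), (4, 5, 1), (5, 5, 2), (2, 4, 3)])
    def test_matches_enumeration(self, na, nb, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=na)
        b = rng.normal(size=nb)
        assert wilcoxon_per_lipid(a, b) == pytest.approx(
            enumeration_wilcoxon(a, b), abs=1e-12
        )

    def test_identical_groups_no_evidence(self):
        p = wilcoxon_per_lipid([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.1, 5.0, size=8)
        b = rng.uniform(0.1, 5.0, size=9)
        assert wilcoxon_per_lipid(a, b) == pytest.approx(
            wilcoxon_per_lipid(np.exp(a), np.exp(b))
        )

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_per_lipid([1.0], [2.0, 3.0])


class TestQValues:
    def test_all_ones(self):
        q = estimate_qvalues(np.ones(5))
        assert np.allclose(q, 1.0)
        assert estimate_pi0(np.ones(5)) == 1.0

    def test_hand_computed_vector(self):
        p = np.array([0.01, 0.02, 0.5, 0.9])
        q = estimate_qvalues(p)  # fixed lambda=0.5 since m < 100 -> pi0 = 0.5
        assert np.allclose(q, [0.02, 0.02, 1 / 3, 0.45], atol=1e-12)

    def test_equals_bh_when_pi0_forced_one(self):
        from scipy.stats import false_discovery_control

        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        q = estimate_qvalues(p, pi0=1.0)
        assert np.allclose(q, false_discovery_control(p, method="bh"), atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=200)
        q = estimate_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            estimate_qvalues(np.array([0.5, 1.5]))

    def test_null_pi0_near_one_large_m(self):
        rng = np.random.default_rng(7)
        pi0s = [estimate_pi0(rng.uniform(size=154)) for _ in range(50)]
        assert np.mean(pi0s) >= 0.9


class TestFoldAndDistance:
    def test_fold_examples(self):
        assert fold_difference([2.0, 2.0], [2.0, 2.0]) == 0.0
        assert fold_difference([4.0, 4.0], [1.0, 1.0]) == 2.0

    def test_fold_antisymmetry(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(1, 5, 11)
        b = rng.uniform(1, 5, 11)
        assert fold_difference(a, b) == pytest.approx(-fold_difference(b, a))

    def test_fold_zero_low_median_rejected(self):
        with pytest.raises(ValueError):
            fold_difference([1.0, 2.0], [0.0, 0.0])

    def test_corr_distance_examples(self):
        x = np.array([1.0, 2.0, 3.0])
        assert corr_distance(x, x) == pytest.approx(0.0, abs=1e-12)
        assert corr_distance(x, -x) == pytest.approx(2.0, abs=1e-12)
        assert corr_distance([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_corr_distance_constant_rejected(self):
        with pytest.raises(ValueError):
            corr_distance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(deadline=None, max_examples=30)
    @given(
        x=st.lists(st.floats(-50, 50), min_size=4, max_size=8),
        y=st.lists(st.floats(-50, 50), min_size=4, max_size=8),
    )
    def test_corr_distance_range_and_symmetry(self, x, y):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]), np.array(y[:n])
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        d = corr_distance(x, y)
        assert -1e-9 <= d <= 2 + 1e-9
        assert d == pytest.approx(corr_distance(y, x), abs=1e-12)


class TestClustering:
    def test_identical_items_merge_at_zero(self):
        rng = np.random.default_rng(9)
        row = rng.normal(size=6)
        M = np.vstack([row, row, rng.normal(size=6)])
        tree = ward_cluster(M)
        assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-9)
        assert set(tree.linkage[0, :2].astype(int)) == {0, 1}

    def test_outlier_merges_last(self):
        t = np.linspace(0, 1, 8)
        M = np.vstack([t, t + 0.01 * np.sin(t), -t])  # rows 0,1 alike; row 2 opposite
        tree = ward_cluster(M)
        # the last merge involves the singleton cluster containing item 2
        assert 2 not in set(tree.linkage[0, :2].astype(int))

    def test_leaf_count_preserved(self):
        rng = np.random.default_rng(10)
        M = rng.normal(size=(7, 5))
        tree = ward_cluster(M)
        assert tree.n_leaves == 7
        assert sorted(tree.leaf_order()) == list(range(7))

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(11)
        tree = ward_cluster(rng.normal(size=(10, 6)))
        assert np.all(np.diff(tree.heights()) >= -1e-12)

    def test_newick_round_trips_leaf_labels(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(12)
        labels = ["PC(16:0/0:0)", "PC(18:0/0:0)", "L000", "L001", "L002"]
        tree = ward_cluster(rng.normal(size=(5, 6)), labels)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == sorted(labels)


class TestHeatmaps:
    def test_identical_groups_zero_ratio(self, toy_dataset):
        ds = toy_dataset
        # make both individuals' profiles identical
        rec = ds.records.copy()
        rec["concentration"] = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        ds.records = rec
        out = ratio_heatmap_matrix(ds)
        assert np.allclose(out.to_numpy(dtype=float), 0.0, equal_nan=True)

    def test_ratio_matrix_shape(self):
        from metaprog.synthetic_data import GeneratorSpec, simulate_cohort

        ds, _ = simulate_cohort(GeneratorSpec(n_metabolites=5, seed=12))
        out = ratio_heatmap_matrix(ds)
        assert out.shape == (5, 34)

    def test_planted_decrease_shows_negative_early_bins(self):
        from metaprog.synthetic_data import GeneratorSpec, default_truth, simulate_cohort

        truth = {
            g: default_truth(4, 3, g, noise_sd=0.1, state_step=0.0)
            for g in ("progressor", "non-progressor")
        }
        truth["progressor"].means[:, 0] -= 1.0  # lipid 0 halved in progressors
        spec = GeneratorSpec(
            n_progressors=10,
            n_nonprogressors=10,
            ages=np.arange(3.0, 13.0),
            n_metabolites=4,
            hmm_truth=truth,
            dropout_hazard=0.0,
            noise_sd=0.1,
            seed=13,
        )
        ds, _ = simulate_cohort(spec)
        out = ratio_heatmap_matrix(ds)
        assert np.nanmean(out.loc["L000"]) < -0.7

    def test_profile_heatmap_normalization(self):
        rng = np.random.default_rng(14)
        profiles = pd.DataFrame(
            rng.uniform(1, 4, size=(12, 5)), columns=[f"v{i}" for i in range(5)]
        )
        groups = pd.Series(["ref"] * 6 + ["other"] * 6)
        scaled, tree = profile_heatmap(profiles, groups, "ref")
        assert np.allclose(scaled.std(axis=0, ddof=0), 1.0, atol=1e-9)
        assert tree.n_leaves == 5
        # doubling the other group's raw values shifts it by +1 pre-scaling
        doubled = profiles.copy()
        doubled.iloc[6:] *= 2.0
        norm_a = np.log2(profiles / profiles.iloc[:6].mean())
        norm_b = np.log2(doubled / doubled.iloc[:6].mean())
        assert np.allclose(norm_b.iloc[6:], norm_a.iloc[6:] + 1.0)

    def test_profile_heatmap_zero_reference_named(self):
        profiles = pd.DataFrame({"v0": [0.0, 0.0, 1.0], "v1": [1.0, 2.0, 3.0]})
        groups = pd.Series(["ref", "ref", "x"])
        with pytest.raises(ValueError, match="v0"):
            profile_heatmap(profiles, groups, "ref")


class TestHomaIR:
    def test_values(self):
        assert homa_ir(22.5, 1.0) == 1.0
        assert homa_ir(10.0, 4.5) == 2.0

    def test_linear_in_each_argument(self):
        assert homa_ir(20.0, 3.0) == pytest.approx(2 * homa_ir(10.0, 3.0))
        assert homa_ir(10.0, 6.0) == pytest.approx(2 * homa_ir(10.0, 3.0))

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            homa_ir(0.0, 4.0)
        with pytest.raises(ValueError):
            homa_ir(5.0, -1.0)
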