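import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spatimet import (
    RegionSpectrum, ScreenConfig, align_peaks, bh_adjust, classify_trend,
    classify_trends, compare_groups, integrate_comparisons,
    simulate_group_matrix,
)
from spatimet.diffstats import DiffResult, VennSummary
from spatimet.preprocess import FeatureTable


def bh_brute_force(p):
    """Step-up definition: q(i) = min_{p(j) >= p(i)} p(j) * m / rank(j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for i in range(m):
        candidates = [p[j] * m / (np.searchsorted(p[order], p[j], side="right"))
                      for j in range(m) if p[j] >= p[i]]
        q[i] = min(1.0, min(candidates))
    return q


class TestBhAdjust:
    def test_textbook_vector(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_itself(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_capped(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=20))
    def test_matches_bruteforce_stepup(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), bh_brute_force(pvals),
                                   atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(0, 1, 50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


def table_from_matrix(matrix, labels):
    """FeatureTable wrapper around a plain two-group matrix."""
    matrix = np.asarray(matrix, float)
    mz = 100.0 + np.arange(matrix.shape[1])
    rows = [
        RegionSpectrum(section_id=f"s{i}", region="PT" if lab else "N",
                       mz=mz, intensity=matrix[i])
        for i, lab in enumerate(labels)
    ]
    return FeatureTable(mz, rows, matrix)


class TestCompareGroups:
    def test_identical_groups_nothing_significant(self, rng):
        block = rng.lognormal(3, 1, (5, 30))
        table = table_from_matrix(np.vstack([block, block]),
                                  [0] * 5 + [1] * 5)
        res = compare_groups(table, {"region": "N"}, {"region": "PT"})
        assert np.all(res.table["log2fc"] == 0)
        assert res.n_significant == 0

    def test_planted_feature_called_up(self):
        X, y, truth = simulate_group_matrix(
            n_features=200, n_differential=1, effect_low=2.0, effect_high=2.0,
            sdlog2=0.2, seed=7)
        idx = int(np.flatnonzero(truth["flag"])[0])
        # force the planted effect upward for a sign-explicit check
        if truth["log2fc"][idx] < 0:
            X[y == 1, idx] = X[y == 1, idx] * 2.0 ** (2 * 2.0)
        table = table_from_matrix(X, y)
        res = compare_groups(table, {"region": "N"}, {"region": "PT"})
        assert res.table["direction"].iloc[idx] == "up"

    def test_fold_change_ratio_identity(self):
        a = np.full((3, 1), 10.0)
        b = np.full((3, 1), 20.0)
        table = table_from_matrix(np.vstack([a, b]), [0, 0, 0, 1, 1, 1])
        cfg = ScreenConfig(pseudo_count=1e-9)
        res = compare_groups(table, {"region": "N"}, {"region": "PT"}, cfg)
        assert res.table["log2fc"].iloc[0] == pytest.approx(1.0)

    def test_label_swap_negates_lfc_preserves_p(self, rng):
        X, y, _ = simulate_group_matrix(n_features=50, n_differential=10,
                                        seed=3)
        table = table_from_matrix(X, y)
        fwd = compare_groups(table, {"region": "N"}, {"region": "PT"})
        rev = compare_groups(table, {"region": "PT"}, {"region": "N"})
        np.testing.assert_allclose(fwd.table["log2fc"],
                                   -rev.table["log2fc"], atol=1e-9)
        np.testing.assert_allclose(fwd.table["p"], rev.table["p"], atol=1e-12)

    def test_small_group_rejected(self, rng):
        table = table_from_matrix(rng.lognormal(3, 1, (5, 4)),
                                  [0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="'A'"):
            compare_groups(table, {"region": "N"}, {"region": "PT"})

    def test_spikein_recall_and_fdp(self):
        """100 planted effects (|log2FC| >= 1) among 1000 features at n=10v10:
        the screen recovers >= 90% with false-discovery proportion <= 10%."""
        X, y, truth = simulate_group_matrix(
            n_features=1000, n_per_group=(10, 10), n_differential=100,
            effect_low=1.0, effect_high=2.0, seed=5)
        table = table_from_matrix(X, y)
        res = compare_groups(table, {"region": "N"}, {"region": "PT"})
        called = set(res.significant())
        true = set(np.flatnonzero(truth["flag"]))
        recall = len(called & true) / len(true)
        fdp = len(called - true) / max(len(called), 1)
        assert recall >= 0.9
        assert fdp <= 0.1

    def test_welch_alternative(self):
        X, y, truth = simulate_group_matrix(
            n_features=300, n_differential=30, effect_low=1.5, seed=8)
        table = table_from_matrix(X, y)
        res = compare_groups(table, {"region": "N"}, {"region": "PT"},
                             ScreenConfig(test="welch_t"))
        called = set(res.significant())
        true = set(np.flatnonzero(truth["flag"]))
        assert len(called & true) / len(true) >= 0.9


def make_diff(directions):
    n = len(directions)
    t = pd.DataFrame({
        "feature_mz": 100.0 + np.arange(n),
        "mean_a": 1.0, "mean_b": 1.0, "log2fc": 0.0, "p": 1.0, "q": 1.0,
        "direction": directions,
    })
    return DiffResult(t, "A", "B", 5, 5)


class TestIntegrateComparisons:
    def test_identical_results(self):
        d = make_diff(["up", "down", "ns", "up"])
        v = integrate_comparisons(d, d)
        assert (v.n_a, v.n_b, v.n_intersection, v.n_union) == (3, 3, 3, 3)
        assert (v.up_up, v.down_down, v.discordant) == (2, 1, 0)

    def test_disjoint_sets(self):
        a = make_diff(["up", "ns", "ns"])
        b = make_diff(["ns", "down", "ns"])
        v = integrate_comparisons(a, b)
        assert v.n_intersection == 0
        assert v.n_union == 2

    def test_mismatched_feature_space_rejected(self):
        with pytest.raises(ValueError, match="feature space"):
            integrate_comparisons(make_diff(["up"]), make_diff(["up", "ns"]))

    def test_union_identity_holds(self, rng):
        dirs = rng.choice(["up", "down", "ns"], 200)
        dirs2 = rng.choice(["up", "down", "ns"], 200)
        v = integrate_comparisons(make_diff(dirs), make_diff(dirs2))
        assert v.n_union == v.n_a + v.n_b - v.n_intersection
        assert v.up_up + v.down_down + v.discordant == v.n_intersection

    def test_venn_invariants_enforced(self):
        with pytest.raises(ValueError):
            VennSummary(n_a=2, n_b=2, n_intersection=3)


class TestClassifyTrend:
    @pytest.mark.parametrize("d1,d2,label", [
        ("up", "up", "monotone_increase"),
        ("down", "down", "monotone_decrease"),
        ("up", "down", "up_then_down"),
        ("down", "up", "down_then_up"),
        ("ns", "ns", "flat"),
        ("up", "ns", "mixed"),
        ("ns", "down", "mixed"),
    ])
    def test_mapping(self, d1, d2, label):
        assert classify_trend(d1, d2) == label

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            classify_trend("sideways", "up")

    def test_vectorized_labels(self):
        a = make_diff(["up", "down", "ns"])
        b = make_diff(["up", "up", "ns"])
        labels = classify_trends(a, b)
        assert list(labels) == ["monotone_increase", "down_then_up", "flat"]


def test_null_simulation_controls_false_discoveries(rng):
    """Global-null replicates: the chance of any BH discovery at alpha=0.05
    stays within Monte-Carlo error of the nominal level."""
    n_rep, n_feat = 200, 1000
    false_hits = 0
    for _ in range(n_rep):
        X, y, _ = simulate_group_matrix(
            n_features=n_feat, n_differential=0,
            seed=int(rng.integers(2 ** 31)))
        table = table_from_matrix(X, y)
        res = compare_groups(table, {"region": "N"}, {"region": "PT"})
        if res.n_significant > 0:
            false_hits += 1
    rate = false_hits / n_rep
    mc_sd = np.sqrt(0.05 * 0.95 / n_rep)
    assert rate <= 0.05 + 2 * mc_sd
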