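import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spatimet import (
    auc_univariate, cv_auc, fit_logistic_panel, fit_panel_with_cv,
    rank_signatures, roc_curve_points, simulate_panel_data,
)
from spatimet.signatures import ConvergenceError


def auc_pair_counting(values, labels):
    """Brute-force definition: concordant + half of tied pairs."""
    pos = [v for v, l in zip(values, labels) if l == 1]
    neg = [v for v, l in zip(values, labels) if l == 0]
    score = 0.0
    for p in pos:
        for n in neg:
            score += 1.0 if p > n else (0.5 if p == n else 0.0)
    return score / (len(pos) * len(neg))


class TestAucUnivariate:
    def test_perfect_separation(self):
        assert auc_univariate([1, 2, 3, 4, 5, 6],
                              [0, 0, 0, 1, 1, 1]) == 1.0

    def test_interleaved(self):
        assert auc_univariate([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75

    def test_all_ties(self):
        assert auc_univariate([5, 5, 5, 5], [0, 0, 1, 1]) == 0.5

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.integers(min_value=-5, max_value=5), min_size=2,
                    max_size=12),
           st.data())
    def test_matches_pair_counting(self, values, data):
        n = len(values)
        n_pos = data.draw(st.integers(min_value=1, max_value=n - 1))
        labels = [1] * n_pos + [0] * (n - n_pos)
        assert auc_univariate(values, labels) == pytest.approx(
            auc_pair_counting(values, labels))

    def test_complement_identity(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        assert auc_univariate(x, y) + auc_univariate(-x, y) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_univariate([1, 2], [1, 1])


class TestRankSignatures:
    def test_tiers_and_sorting(self, rng):
        n = 200
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        strong = rng.normal(0, 1, n) + 2.5 * y  # AUC >> 0.85
        null = rng.normal(0, 1, n)
        ranked = rank_signatures(np.column_stack([null, strong]), y,
                                 ["null", "strong"])
        assert list(ranked["name"]) == ["strong", "null"]
        assert ranked["tier"].iloc[0] == ">=0.85"
        assert ranked["tier"].iloc[1] == "below"

    def test_null_marker_near_half(self, rng):
        n = 400
        y = np.array([0, 1] * (n // 2))
        ranked = rank_signatures(rng.normal(0, 1, (n, 1)), y, ["m"])
        assert abs(ranked["auc"].iloc[0] - 0.5) < 2 / np.sqrt(n)

    def test_orientation_flips_with_labels(self, rng):
        y = np.array([0] * 20 + [1] * 20)
        x = rng.normal(0, 1, 40) + 2 * y
        a = rank_signatures(x[:, None], y, ["m"])
        b = rank_signatures(x[:, None], 1 - y, ["m"])
        assert a["orientation"].iloc[0] == "positive_high"
        assert b["orientation"].iloc[0] == "negative_high"
        assert a["auc_oriented"].iloc[0] == pytest.approx(
            b["auc_oriented"].iloc[0])


class TestLogisticPanel:
    def test_separable_panel_insample_auc_one(self):
        X = np.array([[0, 0], [0.1, 0], [0.9, 1], [1, 1],
                      [0.05, 0.1], [0.95, 0.9]])
        y = np.array([0, 0, 1, 1, 0, 1])
        model = fit_logistic_panel(X, y)
        assert model.auc_insample == 1.0

    def test_duplicated_member_same_auc_as_univariate(self, rng):
        n = 60
        y = np.array([0] * 30 + [1] * 30)
        x = rng.normal(0, 1, n) + 1.5 * y
        uni = auc_univariate(x, y)
        model = fit_logistic_panel(np.column_stack([x, x]), y)
        # AUC is invariant under the monotone logistic transform of x
        assert model.auc_insample == pytest.approx(uni, abs=1e-9)

    def test_permuted_labels_near_chance(self, rng):
        n = 300
        X = rng.normal(0, 1, (n, 4))
        y = rng.permutation([0] * (n // 2) + [1] * (n // 2))
        model = fit_logistic_panel(X, y)
        assert abs(model.auc_insample - 0.5) < 0.12

    def test_agrees_with_reference_implementation(self, rng):
        """On well-conditioned data the near-unpenalized IRLS fit must match
        statsmodels' Newton logistic fit."""
        import statsmodels.api as sm_api

        n = 200
        X = rng.normal(0, 1, (n, 3))
        logits = 0.5 * X[:, 0] - 0.8 * X[:, 2]
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        ours = fit_logistic_panel(X, y, ridge=1e-10)
        ref = sm_api.Logit(y, sm_api.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(ours.intercept, ref.params[0], atol=1e-5)
        np.testing.assert_allclose(ours.coef, ref.params[1:], atol=1e-5)

    def test_monotone_transform_invariance(self, rng):
        X, y = simulate_panel_data(n_samples=80, seed=3)
        model = fit_panel_with_cv(X, y, seed=1)
        scores = model.decision_scores(X)
        transformed = np.tanh(scores / 4) * 7 + 2  # strictly monotone
        assert auc_univariate(transformed, y) == pytest.approx(
            model.auc_insample)

    def test_single_column_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            fit_logistic_panel(rng.normal(0, 1, (10, 1)), [0, 1] * 5)

    def test_nonconvergence_reports_trace(self, rng):
        X = np.column_stack([np.arange(10.0), rng.normal(0, 1, 10)])
        y = (np.arange(10) >= 5).astype(int)
        with pytest.raises(ConvergenceError, match="trace"):
            fit_logistic_panel(X, y, ridge=1e-12, max_iter=2)


class TestCvAuc:
    def test_seed_determinism(self):
        X, y = simulate_panel_data(n_samples=60, seed=5)
        a = cv_auc(X, y, folds=5, seed=9)
        b = cv_auc(X, y, folds=5, seed=9)
        assert a == b

    def test_recovers_planted_separation(self):
        """Planted panel with large-sample AUC 0.95: the CV estimate (averaged
        over replicate draws) lands within +/-0.05 of it at n=60."""
        means = []
        for rep in range(10):
            X, y = simulate_panel_data(n_samples=60, target_auc=0.95,
                                       seed=rep)
            mean, _, _ = cv_auc(X, y, folds=5, seed=rep)
            means.append(mean)
        assert np.mean(means) == pytest.approx(0.95, abs=0.05)

    def test_null_panel_within_chance_envelope(self, rng):
        X = rng.normal(0, 1, (60, 4))
        y = np.array([0] * 30 + [1] * 30)
        mean, _, _ = cv_auc(X, y, folds=5, seed=2)
        assert 0.3 <= mean <= 0.7

    def test_cv_not_optimistic_on_average(self):
        """CV AUC should not exceed in-sample AUC on average (optimism is
        non-negative) over repeated draws."""
        diffs = []
        for rep in range(50):
            X, y = simulate_panel_data(n_samples=40, target_auc=0.9, seed=rep)
            model = fit_logistic_panel(X, y)
            mean, _, _ = cv_auc(X, y, folds=5, seed=rep)
            diffs.append(model.auc_insample - mean)
        assert np.mean(diffs) >= 0

    def test_class_smaller_than_folds_rejected(self, rng):
        X = rng.normal(0, 1, (10, 2))
        y = np.array([1, 1, 1] + [0] * 7)
        with pytest.raises(ValueError, match="fewer folds"):
            cv_auc(X, y, folds=5, seed=0)


def test_roc_curve_points_monotone(rng):
    X, y = simulate_panel_data(n_samples=50, seed=7)
    pts = roc_curve_points(X[:, 0], y)
    assert np.all(np.diff(pts["fpr"]) >= 0)
    assert np.all(np.diff(pts["tpr"]) >= 0)
    assert pts["tpr"].iloc[-1] == 1.0
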