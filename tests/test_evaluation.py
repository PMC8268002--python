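"""ROC/Youden/bootstrap/DeLong diagnostics and the contingency worked examples."""

import itertools

import numpy as np
import pytest
from scipy import stats

from peristas.evaluation import (
    ContingencyTable,
    bootstrap_ci,
    delong_test,
    metrics_from_counts,
    roc_curve_auc,
    youden_threshold,
)

# binary-sign contingency counts of the emulated study cohort
# (sign-positive/negative within 56 STAS+ and 160 STAS- cases)
SIGN_COUNTS = {
    "solid_nodule": ContingencyTable(32, 24, 63, 97),
    "irregular_shape": ContingencyTable(27, 29, 108, 52),
    "cystic_airspaces": ContingencyTable(13, 43, 65, 95),
    "unclear_interface": ContingencyTable(38, 18, 52, 108),
    "satellites": ContingencyTable(14, 42, 6, 154),
}


def brute_force_auc(scores, labels):
    """Exhaustive pair counting: P(score+ > score-) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestContingencyMetrics:
    def test_satellites_row(self):
        rep = metrics_from_counts(SIGN_COUNTS["satellites"])
        assert round(rep.auc, 3) == 0.606
        assert round(rep.sensitivity, 2) == 0.25
        assert round(rep.specificity, 2) == 0.96
        assert round(rep.ppv, 2) == 0.70
        assert round(rep.npv, 2) == 0.79
        assert round(rep.accuracy, 2) == 0.78

    def test_unclear_interface_row(self):
        rep = metrics_from_counts(SIGN_COUNTS["unclear_interface"])
        assert round(rep.auc, 3) == 0.677
        assert round(rep.accuracy, 2) == 0.68
        assert round(rep.ppv, 2) == 0.42
        assert round(rep.npv, 2) == 0.86

    def test_chance_table(self):
        rep = metrics_from_counts(ContingencyTable(5, 5, 5, 5))
        assert rep.auc == 0.5

    def test_zero_denominator_is_nan_not_zero(self):
        with pytest.warns(UserWarning, match="undefined"):
            rep = metrics_from_counts(ContingencyTable(0, 0, 3, 7))
        assert np.isnan(rep.sensitivity)
        assert not np.isnan(rep.specificity)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 5)

    def test_agrees_with_roc_auc_on_binary_scores_exhaustively(self):
        """(sens+spec)/2 equals the Mann-Whitney AUC of the 0/1 predictor."""
        import warnings

        warnings.simplefilter("ignore", UserWarning)
        for tp, fn, fp, tn in itertools.product(range(4), repeat=4):
            if (tp + fn) == 0 or (fp + tn) == 0:
                continue
            scores = [1] * tp + [0] * fn + [1] * fp + [0] * tn
            labels = [1] * (tp + fn) + [0] * (fp + tn)
            rep = metrics_from_counts(ContingencyTable(tp, fn, fp, tn))
            _, _, _, auc = roc_curve_auc(scores, labels)
            assert rep.auc == pytest.approx(auc, abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        _, _, _, auc = roc_curve_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            scores = rng.normal(size=20).round(1)  # rounding forces ties
            labels = rng.integers(0, 2, 20)
            if len(np.unique(labels)) < 2:
                continue
            _, _, _, auc = roc_curve_auc(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        _, _, _, a = roc_curve_auc(scores, labels)
        _, _, _, b = roc_curve_auc(np.exp(2 * scores), labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve_auc([0.1, 0.2], [1, 1])


class TestYouden:
    def test_separable_scores_reach_j_one(self):
        cut, rep = youden_threshold([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert rep.youden_j == pytest.approx(1.0)
        assert 0.2 < cut <= 0.8

    def test_toy_matches_exhaustive_threshold_scan(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        cut, rep = youden_threshold(scores, labels)
        best_j = -np.inf
        for c in np.concatenate([scores, [np.inf]]):
            pred = scores >= c
            sens = (pred & (labels == 1)).sum() / 2
            spec = (~pred & (labels == 0)).sum() / 2
            best_j = max(best_j, sens + spec - 1)
        assert rep.youden_j == pytest.approx(best_j)
        # the scan's optimum here keeps both positives and drops only 0.4
        assert 0.35 < cut <= 0.8 or cut == pytest.approx(0.35)

    def test_j_identity_at_threshold(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        cut, rep = youden_threshold(scores, labels)
        assert rep.youden_j == pytest.approx(rep.sensitivity + rep.specificity - 1)


class TestBootstrap:
    def test_default_resamples_and_determinism(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=60) + np.repeat([1, 0], 30) * 1.2
        labels = np.repeat([1, 0], 30)
        lo1, hi1 = bootstrap_ci(scores, labels, seed=5)
        lo2, hi2 = bootstrap_ci(scores, labels, seed=5)
        assert (lo1, hi1) == (lo2, hi2)
        assert lo1 < hi1

    def test_point_estimate_inside_ci(self):
        rng = np.random.default_rng(4)
        covered = 0
        for seed in range(10):
            scores = rng.normal(size=80) + np.repeat([0.8, 0], 40)
            labels = np.repeat([1, 0], 40)
            _, _, _, auc = roc_curve_auc(scores, labels)
            lo, hi = bootstrap_ci(scores, labels, n_boot=300, seed=seed)
            covered += lo <= auc <= hi
        assert covered >= 9

    def test_ci_narrows_with_sample_size(self):
        rng = np.random.default_rng(5)

        def width(n):
            scores = rng.normal(size=2 * n) + np.repeat([1.0, 0], n)
            labels = np.repeat([1, 0], n)
            lo, hi = bootstrap_ci(scores, labels, n_boot=400, seed=1)
            return hi - lo

        assert width(500) < width(50)

    def test_constant_scores_degenerate_ci(self):
        lo, hi = bootstrap_ci(np.ones(20), np.repeat([1, 0], 10), n_boot=50, seed=0)
        assert (lo, hi) == (0.5, 0.5)


class TestDeLong:
    def test_identical_scores_give_z0_p1(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=40)
        y = np.repeat([1, 0], 20)
        z, p = delong_test(s, s, y)
        assert (z, p) == (0.0, 1.0)

    def test_matches_independent_placement_implementation(self):
        """Loop-based placement values reproduce z within 1e-6 (n=30)."""
        rng = np.random.default_rng(7)
        y = np.array([1] * 12 + [0] * 18)
        a = rng.normal(size=30) + y * 0.8
        b = rng.normal(size=30) + y * 0.3

        def placements(scores):
            pos = scores[y == 1]
            neg = scores[y == 0]
            v10 = np.array([np.mean([(x > n) + 0.5 * (x == n) for n in neg]) for x in pos])
            v01 = np.array([np.mean([(p_ > n_) + 0.5 * (p_ == n_) for p_ in pos]) for n_ in neg])
            return v10, v01

        v10a, v01a = placements(a)
        v10b, v01b = placements(b)
        auc_a, auc_b = v10a.mean(), v10b.mean()
        s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
        s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / 12 + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / 18
        z_expected = (auc_a - auc_b) / np.sqrt(var)
        z, p = delong_test(a, b, y)
        assert z == pytest.approx(z_expected, abs=1e-6)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z_expected)), abs=1e-6)

    def test_clearly_better_model_significant(self):
        rng = np.random.default_rng(8)
        y = np.repeat([1, 0], 100)
        good = rng.normal(size=200) + y * 2.5
        bad = rng.normal(size=200)
        z, p = delong_test(good, bad, y)
        assert p < 0.05  # the study's significance convention

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_test([1, 2, 3], [1, 2], [1, 0, 1])
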