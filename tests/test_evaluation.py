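"""Discrimination, thresholded metrics, calibration, recalibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from itertools import combinations

from radpdl1.evaluation import (bootstrap_ci, brier_score, calibration,
                                classification_metrics, group_compare,
                                isotonic_recalibrate, operating_point,
                                roc_auc)


def _pair_count_auc(scores, labels):
    s = np.asarray(scores)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 10, [0, 1] * 5) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(5):
            s = np.round(rng.random(30), 2)  # rounding forces ties
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            assert roc_auc(s, y) == pytest.approx(_pair_count_auc(s, y),
                                                  abs=1e-12)

    @given(st.floats(0.1, 10.0), st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_invariance_under_monotone_transforms(self, a, b):
        rng = np.random.default_rng(9)
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        base = roc_auc(s, y)
        assert roc_auc(a * s + b, y) == pytest.approx(base, abs=1e-12)
        logit = np.log(s / (1 - s))
        assert roc_auc(logit, y) == pytest.approx(base, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestBootstrap:
    def test_constant_metric_degenerate_interval(self):
        s = np.linspace(0, 1, 20)
        y = (s > 0.5).astype(int)
        lo, hi = bootstrap_ci(lambda a, b: 42.0, s, y, n_boot=100, seed=0)
        assert lo == hi == 42.0

    def test_same_seed_identical_interval(self):
        rng = np.random.default_rng(1)
        s, y = rng.random(50), rng.integers(0, 2, 50)
        ci1 = bootstrap_ci(roc_auc, s, y, n_boot=200, seed=3)
        ci2 = bootstrap_ci(roc_auc, s, y, n_boot=200, seed=3)
        assert ci1 == ci2

    def test_interval_contains_point_estimate(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, 60)
            s = np.clip(0.5 + 0.3 * (y - 0.5) + rng.normal(0, 0.2, 60), 0, 1)
            lo, hi = bootstrap_ci(roc_auc, s, y, n_boot=300, seed=seed)
            hits += lo <= roc_auc(s, y) <= hi
        assert hits >= 19


class TestOperatingPoint:
    def test_matches_exhaustive_scan(self):
        s = np.array([.1, .2, .3, .4, .5, .6, .7, .8, .9, 1.0])
        y = np.array([0, 0, 1, 0, 1, 0, 1, 1, 0, 1])
        thr = operating_point(s, y, 0.7)
        # oracle: largest threshold among candidates with sens >= 0.7
        best = max(t for t in s if (s[y == 1] >= t).mean() >= 0.7)
        assert thr == best == 0.5

    def test_target_one_thresholds_below_min_positive(self):
        s = np.array([.2, .4, .6, .8])
        y = np.array([0, 1, 0, 1])
        thr = operating_point(s, y, 1.0)
        assert thr <= 0.4
        assert (s[y == 1] >= thr).mean() == 1.0

    def test_target_zero_picks_largest_threshold(self):
        s = np.array([.2, .4, .6, .8])
        y = np.array([0, 1, 0, 1])
        assert operating_point(s, y, 0.0) == 0.8

    def test_no_positive_cases_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            operating_point(np.array([.2, .4]), np.array([0, 0]), 0.7)


class TestClassificationMetrics:
    def test_hand_worked_confusion(self):
        # TP=30 FP=10 FN=10 TN=50 at threshold 0.5
        s = np.r_[np.full(40, 0.9), np.full(60, 0.1)]
        y = np.r_[np.ones(30), np.zeros(10), np.ones(10), np.zeros(50)]
        m = classification_metrics(s, y, 0.5)
        assert (m.tp, m.fp, m.fn, m.tn) == (30, 10, 10, 50)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.accuracy == pytest.approx(0.80)
        assert m.f1 == pytest.approx(0.75)
        assert m.specificity == pytest.approx(50 / 60)

    def test_perfect_classifier(self):
        s = np.array([0.9, 0.95, 0.1, 0.05])
        y = np.array([1, 1, 0, 0])
        m = classification_metrics(s, y, 0.5)
        assert m.fp == m.fn == 0
        assert m.accuracy == m.precision == m.recall == m.f1 == 1.0

    def test_threshold_above_max_score(self):
        s = np.array([0.2, 0.4, 0.6])
        y = np.array([1, 0, 1])
        m = classification_metrics(s, y, 0.99)
        assert m.recall == 0.0
        assert m.specificity == 1.0
        assert m.precision is None  # undefined, not NaN

    def test_counts_conserved_at_any_threshold(self, rng):
        s, y = rng.random(37), rng.integers(0, 2, 37)
        for thr in (0.0, 0.3, 0.72, 1.1):
            m = classification_metrics(s, y, thr)
            assert m.tp + m.fp + m.fn + m.tn == 37


class TestCalibration:
    def test_perfect_scores_zero_brier(self):
        y = np.array([0, 1, 1, 0] * 5)
        _, brier = calibration(y.astype(float), y, n_bins=5)
        assert brier == 0.0

    def test_all_half_scores_quarter_brier(self, rng):
        y = rng.integers(0, 2, 40)
        assert brier_score(np.full(40, 0.5), y) == pytest.approx(0.25)

    def test_well_calibrated_curve_near_diagonal(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 5000)
        y = (rng.random(5000) < p).astype(int)
        curve, _ = calibration(p, y, n_bins=10)
        for mean_pred, obs, count in curve:
            assert abs(mean_pred - obs) < 0.05

    def test_brier_nonnegative_zero_iff_exact(self, rng):
        s, y = rng.random(30), rng.integers(0, 2, 30)
        assert brier_score(s, y) > 0
        assert brier_score(y.astype(float), y) == 0.0


class TestIsotonic:
    def test_matches_hand_run_pav(self):
        # pool-adjacent-violators by hand: [0,0,1,0,...] pools the (1,0)
        # inversion to 0.5; [...,1,1,0,...] pools (1,1,0) to 2/3
        s = np.arange(1, 11, dtype=float)
        y = np.array([0, 0, 1, 0, 1, 1, 0, 1, 1, 1])
        f = isotonic_recalibrate(s, y)
        expected = [0, 0, 0.5, 0.5, 2 / 3, 2 / 3, 2 / 3, 1, 1, 1]
        assert np.allclose(f(s), expected)

    def test_never_increases_brier_on_fit_set(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            s = r.random(40)
            y = r.integers(0, 2, 40)
            f = isotonic_recalibrate(s, y)
            assert brier_score(f(s), y) <= brier_score(s, y) + 1e-12

    def test_monotone_everywhere(self, rng):
        s, y = rng.random(50), rng.integers(0, 2, 50)
        f = isotonic_recalibrate(s, y)
        grid = f(np.linspace(0, 1, 500))
        assert np.all(np.diff(grid) >= -1e-12)

    def test_cv_variant_is_monotone_and_bounded(self, rng):
        s, y = rng.random(60), rng.integers(0, 2, 60)
        f = isotonic_recalibrate(s, y, n_folds=5, seed=0)
        grid = f(np.linspace(0, 1, 300))
        assert np.all(np.diff(grid) >= -1e-12)
        assert grid.min() >= 0 and grid.max() <= 1

    def test_one_class_fit_constant_map(self):
        with pytest.warns(UserWarning, match="one-class"):
            f = isotonic_recalibrate(np.linspace(0, 1, 12), np.ones(12))
        assert np.allclose(f(np.array([0.1, 0.9])), 1.0)


class TestGroupCompare:
    def test_identical_groups(self):
        s = np.r_[np.arange(10.0), np.arange(10.0)]
        y = np.r_[np.ones(10), np.zeros(10)]
        p, d = group_compare(s, y)
        assert d == 0.0
        assert p > 0.9

    def test_exact_p_matches_enumeration(self):
        # {1,2,3} vs {4,5,6}: extreme ranks both ways = 2 of C(6,3)=20
        s = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1])
        p, d = group_compare(s, y)
        assert p == pytest.approx(0.1, abs=1e-12)
        assert d > 0

    def test_effect_size_recovery_near_nominal(self):
        # groups N(0,1) vs N(0.91,1): the reported standardized separation
        ds = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            s = np.r_[r.normal(0.91, 1, 200), r.normal(0, 1, 200)]
            y = np.r_[np.ones(200), np.zeros(200)]
            ds.append(group_compare(s, y)[1])
        assert 0.6 <= float(np.median(ds)) <= 1.2
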