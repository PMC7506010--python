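"""Feature extraction statistics and CFS selection.

The CFS oracle is an exhaustive search over all subsets (feasible for
<= 12 features), independent of the best-first implementation.
"""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sstats

from armscore.features import (
    catalog_for,
    cfs_merit,
    cfs_select,
    extract_features,
    safe_corr,
    series_stats,
)
from armscore.simulate import SimConfig, simulate_subject
from armscore.types import SensorChannel, SensorTrial


def exhaustive_cfs(X, y, max_k=None):
    """Brute-force best-merit subset (oracle)."""
    p = X.shape[1]
    best, best_m = (), 0.0
    for k in range(1, (max_k or p) + 1):
        for subset in combinations(range(p), k):
            m = cfs_merit(X, y, subset)
            if m > best_m + 1e-12:
                best, best_m = subset, m
    return set(best), best_m


class TestSeriesStats:
    def test_constant_series(self):
        s = series_stats(np.full(100, 2.5))
        assert s["min"] == s["max"] == s["mean"] == 2.5
        assert s["rms"] == 2.5
        assert s["entropy"] == 0.0
        assert s["skew"] == 0.0 and s["kurtosis"] == 0.0

    def test_skew_kurtosis_match_bias_corrected_convention(self, rng):
        x = rng.gamma(2.0, size=500)
        s = series_stats(x)
        assert s["skew"] == pytest.approx(sstats.skew(x, bias=False), abs=1e-10)
        assert s["kurtosis"] == pytest.approx(
            sstats.kurtosis(x, fisher=True, bias=False), abs=1e-10
        )

    def test_standard_normal_moments_near_zero(self, rng):
        x = rng.standard_normal(100_000)
        s = series_stats(x)
        assert abs(s["skew"]) < 0.05
        assert abs(s["kurtosis"]) < 0.1

    def test_dominant_frequency_ratio_of_pure_tone(self):
        # bin-aligned tone (100 cycles in 1000 samples): no leakage
        t = np.arange(1000) / 50.0
        s = series_stats(np.sin(2 * np.pi * 5.0 * t))
        assert s["domfreq_ratio"] == pytest.approx(1.0, abs=1e-9)

    def test_dominant_frequency_ratio_bounds(self, rng):
        s = series_stats(rng.normal(size=256))
        assert 0.0 < s["domfreq_ratio"] <= 1.0


class TestSafeCorr:
    def test_identical_series(self, rng):
        x = rng.normal(size=50)
        assert safe_corr(x, x) == pytest.approx(1.0)

    def test_constant_series_defined_as_zero(self, rng):
        assert safe_corr(np.ones(50), rng.normal(size=50)) == 0.0


class TestExtractFeatures:
    def test_catalog_order_deterministic_across_trials(self, tiny_cohort):
        trials = tiny_cohort[0].trials
        cat = catalog_for(trials[0].channels.keys())
        va = extract_features(trials[0], catalog=cat)
        vb = extract_features(trials[5], catalog=cat)
        assert va.names == vb.names == list(cat.names)
        assert np.all(np.isfinite(va.values))

    def test_duration_feature_equals_marker_window(self, tiny_cohort):
        trial = tiny_cohort[0].trials[0]
        vec = extract_features(trial)
        dur = vec.values[vec.names.index("duration")]
        assert dur == pytest.approx(
            (trial.end_marker - trial.start_marker) / trial.fs
        )

    def test_identical_chest_and_wrist_correlate_perfectly(self):
        rng = np.random.default_rng(3)
        fs, n = 50.0, 400
        sig = rng.normal(size=(n, 3))
        trial = SensorTrial(
            "WMFT-1", 1,
            {
                "chest": SensorChannel("chest", sig, fs),
                "wrist_affected": SensorChannel("wrist_affected", sig, fs),
            },
        )
        vec = extract_features(trial)
        r = vec.values[vec.names.index("corr.chest.wrist_affected")]
        assert r == pytest.approx(1.0, abs=1e-9)


class TestCFS:
    def test_single_feature_merit_is_its_correlation(self, rng):
        y = rng.normal(size=200)
        x = 0.75 * y + rng.normal(size=200)
        X = np.column_stack([x, rng.normal(size=200)])
        r = abs(np.corrcoef(X[:, 0], y)[0, 1])
        assert cfs_merit(X, y, [0]) == pytest.approx(r, abs=1e-12)

    def test_two_uncorrelated_features_merit_formula(self):
        # construct exact r_cf = 0.5, r_ff = 0 via orthogonal design
        n = 8
        f1 = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        f2 = np.array([1.0, 1, -1, -1, 1, 1, -1, -1])
        y = 0.5 * f1 + 0.5 * f2 + np.array([1.0, -1, -1, 1, 1, -1, -1, 1])
        X = np.column_stack([f1, f2])
        r1 = abs(np.corrcoef(f1, y)[0, 1])
        expected = 2 * r1 / np.sqrt(2)
        assert cfs_merit(X, y, [0, 1]) == pytest.approx(expected, abs=1e-12)
        assert abs(np.corrcoef(f1, f2)[0, 1]) < 1e-12

    def test_duplicate_of_target_is_selected(self, rng):
        y = rng.normal(size=100)
        X = np.column_stack([rng.normal(size=(100, 5)), y])
        mask = cfs_select(X, y)
        assert mask[5]
        oracle, _ = exhaustive_cfs(X, y, max_k=3)
        assert 5 in oracle

    def test_constant_target_raises(self, rng):
        with pytest.raises(ValueError):
            cfs_select(rng.normal(size=(30, 4)), np.ones(30))

    def test_all_constant_features_empty_mask(self):
        with pytest.warns(UserWarning):
            mask = cfs_select(np.ones((30, 4)), np.arange(30.0))
        assert not mask.any()

    def test_best_first_matches_exhaustive_on_small_problems(self):
        # measured property: >= 95% agreement over random instances
        rng = np.random.default_rng(2024)
        hits = 0
        trials = 40
        for _ in range(trials):
            n, p = 40, rng.integers(6, 11)
            beta = np.where(rng.random(p) < 0.4, rng.normal(0, 1, p), 0.0)
            X = rng.normal(size=(n, p))
            y = X @ beta + rng.normal(size=n)
            mask = cfs_select(X, y)
            got = cfs_merit(X, y, np.flatnonzero(mask))
            _, best = exhaustive_cfs(X, y)
            if got >= best - 1e-12:
                hits += 1
        assert hits >= 0.95 * trials
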