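"""Synthetic cohort generator: determinism, substream independence, and
the impairment -> signal monotonicities the estimators rely on."""

import numpy as np
import pytest
from scipy import stats as sstats

from armscore.dsp import bandfilter, derive_kinematics, segment_trial
from armscore.simulate import (
    FMA_CLASS_RANGES,
    SimConfig,
    draw_fma,
    simulate_cohort,
    simulate_subject,
)
from armscore.types import SensorChannel


def _wrist_jerk_rms(session, normalized=False):
    """Mean RMS jerk of the affected wrist; ``normalized`` rescales by
    duration and acceleration (T·RMS(jerk)/RMS(acc)), the dimensionless
    smoothness reading that removes the faster-movement confound."""
    vals = []
    for trial in session.trials:
        seg = segment_trial(trial)
        ch = seg.channels["wrist_affected"]
        filt = bandfilter(ch.samples, ch.fs)
        kin = derive_kinematics(SensorChannel(ch.placement, filt, ch.fs))
        rms_jerk = np.sqrt(np.mean(kin.jerk**2))
        if normalized:
            T = seg.n_samples / seg.fs
            rms_acc = np.sqrt(np.mean(kin.acceleration**2))
            vals.append(T * rms_jerk / rms_acc)
        else:
            vals.append(rms_jerk)
    return float(np.mean(vals))


def _mean_duration(session):
    return float(np.mean([
        (t.end_marker - t.start_marker) / t.fs for t in session.trials
    ]))


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_subjects=2, reps_per_task=1, seed=5)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        for sa, sb in zip(a, b):
            assert sa.fma_true == sb.fma_true
            assert sa.fas_true_per_task == sb.fas_true_per_task
            for ta, tb in zip(sa.trials, sb.trials):
                for p in ta.channels:
                    np.testing.assert_array_equal(
                        ta.channels[p].samples, tb.channels[p].samples
                    )

    def test_subject_streams_independent_of_cohort_size(self):
        small = simulate_cohort(SimConfig(n_subjects=3, reps_per_task=1, seed=5))
        large = simulate_cohort(SimConfig(n_subjects=5, reps_per_task=1, seed=5))
        for sa, sb in zip(small, large):
            assert sa.fma_true == sb.fma_true
            np.testing.assert_array_equal(
                sa.trials[0].channels["chest"].samples,
                sb.trials[0].channels["chest"].samples,
            )


class TestFmaSampling:
    def test_degenerate_weights_confine_scores(self):
        cfg = SimConfig(fma_class_weights=(1, 0, 0, 0, 0))
        vals = [
            draw_fma(np.random.default_rng(i), cfg.fma_class_weights)
            for i in range(200)
        ]
        assert max(vals) <= 30

    def test_subject_count(self):
        cfg = SimConfig(n_subjects=5, reps_per_task=1, seed=1)
        assert len(simulate_cohort(cfg)) == 5

    def test_class_frequencies_match_weights_multinomially(self):
        cfg = SimConfig()
        w = np.asarray(cfg.fma_class_weights, float)
        p = w / w.sum()
        n = 1000
        rng = np.random.default_rng(99)
        vals = np.array([draw_fma(rng, w) for _ in range(n)])
        edges = [r[1] for r in FMA_CLASS_RANGES[:-1]]
        cls = np.searchsorted(edges, vals, side="left") + 1
        counts = np.bincount(cls, minlength=6)[1:]
        se = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) <= 3 * se)

    def test_out_of_range_fma_rejected(self):
        with pytest.raises(ValueError):
            simulate_subject(70, SimConfig(), np.random.default_rng(0))


@pytest.fixture(scope="module")
def graded_cohort():
    # fixed FMA grid instead of random draws: spans the full range
    cfg = SimConfig(n_subjects=1, reps_per_task=1, seed=11)
    fmas = np.linspace(2, 66, 33).round().astype(int)
    sessions = []
    for i, fma in enumerate(fmas):
        rng = np.random.default_rng(np.random.SeedSequence([11, i]))
        sessions.append(
            simulate_subject(int(fma), cfg, rng, subject_id=f"G{i:03d}")
        )
    return sessions


class TestImpairmentMonotonicity:
    def test_duration_increases_with_impairment(self, graded_cohort):
        fma = [s.fma_true for s in graded_cohort]
        dur = [_mean_duration(s) for s in graded_cohort]
        rho = sstats.spearmanr(fma, dur).statistic
        assert rho < -0.5

    def test_jerk_increases_with_impairment(self, graded_cohort):
        fma = [s.fma_true for s in graded_cohort]
        jerk = [_wrist_jerk_rms(s) for s in graded_cohort]
        rho = sstats.spearmanr(fma, jerk).statistic
        assert rho < -0.5

    def test_unimpaired_noiseless_subject_has_minimal_normalized_jerk(self):
        # zero-impairment limit: no tremor, no fragmentation, so the
        # duration-normalized jerk is minimal over the FMA grid
        cfg = SimConfig(
            n_subjects=1, reps_per_task=1, noise_sd=0.0, tremor_gain=0.0,
            seed=2,
        )
        jerks = []
        for fma in (66, 40, 10):
            s = simulate_subject(fma, cfg, np.random.default_rng(4))
            jerks.append(_wrist_jerk_rms(s, normalized=True))
        assert jerks[0] == min(jerks)

    def test_chest_wrist_coupling_rises_with_impairment(self, graded_cohort):
        fma, coup = [], []
        for s in graded_cohort:
            rs = []
            for trial in s.trials[:4]:
                seg = segment_trial(trial)
                f = {
                    p: bandfilter(seg.channels[p].samples, seg.fs)
                    for p in ("chest", "wrist_affected")
                }
                mags = {
                    p: np.linalg.norm(v, axis=1) for p, v in f.items()
                }
                rs.append(np.corrcoef(mags["chest"], mags["wrist_affected"])[0, 1])
            fma.append(s.fma_true)
            coup.append(np.mean(rs))
        rho = sstats.spearmanr(fma, coup).statistic
        assert rho < -0.5

    def test_fas_fma_cohort_correlation_strong(self, graded_cohort):
        fma = np.array([s.fma_true for s in graded_cohort], float)
        fas = np.array([
            np.mean(list(s.fas_true_per_task.values())) for s in graded_cohort
        ])
        r = np.corrcoef(fma, fas)[0, 1]
        assert r >= 0.8

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(fma_class_weights=(1, 2, 3)).validate()
        with pytest.raises(ValueError):
            SimConfig(fs=10.0).validate()
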