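"""Reference onsets, scoring metrics and cross-validation."""

import numpy as np
import pytest
from scipy.optimize import brentq

import emgonset as eo
from emgonset.detectors import DetectionResult, DetectorConfig, DetectorType
from emgonset.evaluation import (
    PerformanceReport,
    UnscorableTrial,
    correlate_info_performance,
    reference_onset,
    score_detector,
)
from emgonset.io import CHANNEL_NAMES, Event, TrialSegmentation
from emgonset.synthetic import _min_jerk


def _recording(n, fs=1000.0, angles=None, torque=None, led=None):
    rng = np.random.default_rng(0)
    return eo.Recording(
        sample_rate=fs,
        emg=rng.normal(scale=1e-5, size=(n, 7)),
        channel_names=CHANNEL_NAMES,
        joint_angles=angles if angles is not None else np.zeros((n, 4)),
        torque_eFE=torque if torque is not None else np.zeros(n),
        led_state=led if led is not None else np.zeros(n, dtype=int),
        control_mode=np.zeros(n, dtype=int),
    )


class TestReferenceOnset:
    def test_minimum_jerk_ten_percent_crossing(self):
        fs, n = 1000.0, 10000
        t = np.arange(n) / fs
        start, dur, amp = 4.0, 1.2, 30.0
        angles = np.zeros((n, 4))
        angles[:, 1] = amp * _min_jerk(t, start, dur)
        rec = _recording(n, fs, angles=angles)
        trial = TrialSegmentation(0, Event.GO_FORWARD, (1000, 3500), (3500, 8000))
        t0 = reference_onset(rec, trial)
        # closed-form oracle: solve 10 s^3 - 15 s^4 + 6 s^5 = 0.1
        s10 = brentq(lambda s: 10 * s**3 - 15 * s**4 + 6 * s**5 - 0.1, 0, 1)
        assert t0 == pytest.approx(start + s10 * dur, abs=1.0 / fs)

    def test_torque_ramp_crossing(self):
        fs, n = 1000.0, 12000
        t = np.arange(n) / fs
        torque = np.clip((t - 8.0) * 4.0, 0, None)  # crosses 2 N*m at t=8.5
        rec = _recording(n, fs, torque=torque)
        trial = TrialSegmentation(0, Event.GO_BACKWARD, (3000, 7000), (7000, 11000))
        assert reference_onset(rec, trial) == pytest.approx(8.5, abs=1.0 / fs)

    def test_flat_kinematics_unscorable(self):
        rec = _recording(8000)
        trial = TrialSegmentation(0, Event.GO_FORWARD, (1000, 3000), (3000, 6000))
        with pytest.raises(UnscorableTrial):
            reference_onset(rec, trial)

    def test_earliest_joint_wins(self):
        fs, n = 1000.0, 10000
        t = np.arange(n) / fs
        angles = np.zeros((n, 4))
        angles[:, 0] = 20 * _min_jerk(t, 4.5, 1.0)
        angles[:, 2] = 25 * _min_jerk(t, 4.0, 1.0)  # starts earlier
        rec = _recording(n, fs, angles=angles)
        trial = TrialSegmentation(0, Event.GO_FORWARD, (1000, 3500), (3500, 9000))
        t0_both = reference_onset(rec, trial)
        angles2 = angles.copy()
        angles2[:, 2] = 0.0
        t0_late = reference_onset(_recording(n, fs, angles=angles2), trial)
        assert t0_both < t0_late


def _result(times, labels, onsets):
    cfg = DetectorConfig(detector_type=DetectorType.TYPE2, muscles=("a", "b"))
    return DetectionResult(
        labels=np.asarray(labels, dtype=np.uint8), times=np.asarray(times),
        onsets=np.asarray(onsets, dtype=float), theta_traces={}, config=cfg,
    )


def _trials_with_t0(t0s, event=Event.GO_FORWARD):
    out = []
    for k, t0 in enumerate(t0s):
        tr = TrialSegmentation(k, event, (k * 100, k * 100 + 10),
                               (k * 100 + 10, k * 100 + 90))
        tr.t0_reference = t0
        out.append(tr)
    return out


class TestScoreDetector:
    def test_oracle_detector_perfect(self):
        times = np.arange(2000) * 0.01
        rest_labels = np.zeros(2000, dtype=np.int8)
        labels = np.zeros(2000, dtype=np.uint8)
        t0s = [2.0, 7.0, 12.0]
        onsets = np.array(t0s)
        for t0 in t0s:
            sel = (times >= t0) & (times < t0 + 2.0)
            labels[sel] = 1
            rest_labels[sel] = 1
        report = score_detector(
            _result(times, labels, onsets), _trials_with_t0(t0s), 1000.0,
            rest_labels=rest_labels,
        )
        assert report.sensitivity == 100.0
        assert report.specificity == 100.0
        assert report.latency_mean == 0.0

    def test_hand_constructed_counts(self):
        """10 trials, 8 hit; 30 movement labels among 1000 rest steps."""
        times = np.arange(1000) * 0.01
        labels = np.zeros(1000, dtype=np.uint8)
        labels[:30] = 1
        rest_labels = np.zeros(1000, dtype=np.int8)  # every step is rest phase
        t0s = [100.0 + 10 * k for k in range(10)]
        onsets = np.array(t0s[:8]) + 0.2  # 8 inside the window, 2 missed
        report = score_detector(
            _result(times, labels, onsets), _trials_with_t0(t0s), 1000.0,
            rest_labels=rest_labels,
        )
        assert report.TP == 8 and report.FN == 2
        assert report.sensitivity == pytest.approx(80.0, abs=1e-12)
        assert report.TN == 970 and report.FP == 30
        assert report.specificity == pytest.approx(97.0, abs=1e-12)

    def test_anticipation_latency(self):
        times = np.arange(1000) * 0.01
        t0s = [2.0, 4.0, 6.0]
        onsets = np.array(t0s) - 0.100
        report = score_detector(
            _result(times, np.zeros(1000), onsets), _trials_with_t0(t0s), 1000.0,
            rest_labels=np.full(1000, -1, dtype=np.int8),
        )
        assert report.latency_median == pytest.approx(-0.100, abs=1e-12)

    def test_time_shift_invariance(self):
        times = np.arange(1000) * 0.01
        t0s = [2.0, 5.0]
        onsets = np.array([1.9, 5.3])
        r1 = score_detector(_result(times, np.zeros(1000), onsets),
                            _trials_with_t0(t0s), 1000.0,
                            rest_labels=np.full(1000, -1, dtype=np.int8))
        shift = 3.0
        r2 = score_detector(_result(times, np.zeros(1000), onsets + shift),
                            _trials_with_t0([t + shift for t in t0s]), 1000.0,
                            rest_labels=np.full(1000, -1, dtype=np.int8))
        assert r1.sensitivity == r2.sensitivity
        np.testing.assert_allclose(r1.latencies, r2.latencies, atol=1e-12)

    def test_sensitivity_monotone_in_window(self):
        times = np.arange(1000) * 0.01
        t0s = [2.0, 5.0, 8.0]
        onsets = np.array([1.6, 5.9, 8.05])
        rest = np.full(1000, -1, dtype=np.int8)
        wide = score_detector(_result(times, np.zeros(1000), onsets),
                              _trials_with_t0(t0s), 1000.0, t_pre=0.5, t_post=1.0,
                              rest_labels=rest)
        narrow = score_detector(_result(times, np.zeros(1000), onsets),
                                _trials_with_t0(t0s), 1000.0, t_pre=0.1, t_post=0.1,
                                rest_labels=rest)
        assert narrow.sensitivity <= wide.sensitivity

    def test_no_scorable_trials_error(self):
        times = np.arange(100) * 0.01
        trials = [TrialSegmentation(0, Event.GO_FORWARD, (0, 10), (10, 90))]
        with pytest.raises(ValueError, match="scorable"):
            score_detector(_result(times, np.zeros(100), []), trials, 1000.0)


class TestCrossValidation:
    def test_two_sessions_two_rotations(self, small_subject):
        _, recs, gts = small_subject
        cfg = DetectorConfig(
            detector_type=DetectorType.TYPE2,
            muscles=("AnteriorDeltoid", "PosteriorDeltoid", "Biceps"),
        )
        cv = eo.session_cross_validation(
            recs, cfg, Event.GO_FORWARD, ground_truths=gts
        )
        assert len(cv.reports) == 2
        assert cv.sensitivity > 80.0

    def test_deterministic_across_runs(self, small_subject):
        _, recs, gts = small_subject
        cfg = DetectorConfig(
            detector_type=DetectorType.TYPE1, muscles=("AnteriorDeltoid",)
        )
        cv1 = eo.session_cross_validation(recs, cfg, Event.GO_FORWARD,
                                          ground_truths=gts)
        cv2 = eo.session_cross_validation(recs, cfg, Event.GO_FORWARD,
                                          ground_truths=gts)
        assert cv1.sensitivity == cv2.sensitivity
        assert cv1.specificity == cv2.specificity
        np.testing.assert_array_equal(cv1.pooled().latencies,
                                      cv2.pooled().latencies)

    def test_identical_sessions_exchangeable(self, small_subject):
        _, recs, gts = small_subject
        trio = [recs[0]] * 3
        cfg = DetectorConfig(detector_type=DetectorType.TYPE1,
                             muscles=("AnteriorDeltoid",))
        cv = eo.session_cross_validation(trio, cfg, Event.GO_FORWARD,
                                         ground_truths=[gts[0]] * 3)
        assert len(cv.reports) == 6
        sens = {r.sensitivity for r in cv.reports}
        spec = {r.specificity for r in cv.reports}
        assert len(sens) == 1 and len(spec) == 1

    def test_subject_holdout_runs(self, small_subject):
        from emgonset.evaluation import subject_holdout_validation
        _, recs, gts = small_subject
        subjects = {"s1": [recs[0]], "s2": [recs[1]]}
        truths = {"s1": [gts[0]], "s2": [gts[1]]}
        cfg = DetectorConfig(detector_type=DetectorType.TYPE2,
                             muscles=("AnteriorDeltoid", "PosteriorDeltoid",
                                      "Biceps"))
        out = subject_holdout_validation(subjects, cfg, Event.GO_FORWARD,
                                         ground_truths=truths)
        assert set(out) == {"s1", "s2"}
        for res in out.values():
            assert len(res.reports) == 1
            assert res.sensitivity > 80.0

    def test_single_session_rejected(self, small_subject):
        _, recs, _ = small_subject
        cfg = DetectorConfig(detector_type=DetectorType.TYPE1,
                             muscles=("Biceps",))
        with pytest.raises(ValueError, match="2 sessions"):
            eo.session_cross_validation(recs[:1], cfg, Event.GO_FORWARD)


class TestCorrelation:
    def test_perfect_linear(self):
        perf = np.array([10.0, 20.0, 30.0, 40.0])
        out = correlate_info_performance(perf, {"IAV": perf * 0.01 + 3})
        r, p = out["IAV"]
        assert r == pytest.approx(1.0)

    def test_anticorrelated(self):
        perf = np.array([10.0, 20.0, 30.0, 40.0])
        out = correlate_info_performance(perf, {"IAV": -perf})
        assert out["IAV"][0] == pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        perf = rng.random(20)
        info = 0.3 * perf + rng.normal(scale=0.01, size=20)
        r1 = correlate_info_performance(perf, {"f": info})["f"][0]
        r2 = correlate_info_performance(5 * perf + 2, {"f": 0.1 * info - 7})["f"][0]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="3"):
            correlate_info_performance(np.array([1.0, 2.0]), {})
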