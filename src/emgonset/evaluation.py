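"""Reference onsets, detector scoring and session-wise cross-validation.

Detectors are scored against *reference onsets* derived from signals
independent of the EMG: for Go-forward, the first time any joint angle's
excursion from its rest baseline reaches 10% of its trial peak; for
Go-backward, the first time the elbow torque crosses the 2 N·m arming
threshold after the LED turns off.

Three metrics are reported:

* **sensitivity** (event-wise): fraction of trials with at least one
  detected onset inside an acceptance window around the reference onset;
* **specificity** (sample-wise): fraction of rest-phase feature steps
  not labeled movement;
* **latency**: signed delay between the first qualifying detection and
  the reference onset (negative values anticipate the overt movement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .detectors import DetectionResult, DetectorConfig, run_detector
from .features import FeatureSeries, WindowSpec, feature_matrix
from .gmm import GmmParams, em_fit
from .io import Event, ProtocolTiming, Recording, TrialSegmentation, segment_trials

__all__ = [
    "PerformanceReport",
    "reference_onset",
    "score_detector",
    "session_cross_validation",
    "subject_holdout_validation",
    "train_models",
    "correlate_info_performance",
]


@dataclass
class PerformanceReport:
    """Event-wise and sample-wise detector scores for one evaluation."""

    event: Event
    detector: str
    TP: int
    FN: int
    TN: int
    FP: int
    latencies: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def sensitivity(self) -> float:
        """Percent of onset events correctly identified."""
        total = self.TP + self.FN
        return 100.0 * self.TP / total if total else float("nan")

    @property
    def specificity(self) -> float:
        """Percent of rest-phase steps not classified as movement."""
        total = self.TN + self.FP
        return 100.0 * self.TN / total if total else float("nan")

    @property
    def latency_mean(self) -> float:
        return float(np.mean(self.latencies)) if self.latencies.size else float("nan")

    @property
    def latency_median(self) -> float:
        return float(np.median(self.latencies)) if self.latencies.size else float("nan")

    @property
    def latency_iqr(self) -> tuple[float, float]:
        if not self.latencies.size:
            return (float("nan"), float("nan"))
        lo, hi = np.percentile(self.latencies, [25, 75])
        return (float(lo), float(hi))

    def summary(self) -> str:
        lo, hi = self.latency_iqr
        return (
            f"{self.event.value} / {self.detector}: "
            f"sensitivity {self.sensitivity:.1f}% ({self.TP}/{self.TP + self.FN}), "
            f"specificity {self.specificity:.1f}%, "
            f"latency median {self.latency_median:+.3f} s "
            f"(IQR {lo:+.3f} .. {hi:+.3f})"
        )


class UnscorableTrial(ValueError):
    """Raised when a trial's reference signals cannot define an onset."""


def reference_onset(
    rec: Recording,
    trial: TrialSegmentation,
    timing: ProtocolTiming | None = None,
    peak_fraction: float = 0.1,
    noise_floor_deg: float = 1.0,
) -> float:
    """Reference onset time (s) of one trial from kinematics or torque.

    Go-forward: per joint, excursion is the absolute deviation from the
    rest-interval baseline; the onset candidate is the first time within
    the movement window that the excursion reaches ``peak_fraction`` of
    its own peak.  The earliest candidate across joints whose peak
    clears ``noise_floor_deg`` is returned.  Go-backward: first sample
    after LED-off where the elbow torque reaches the arming threshold.
    Raises :class:`UnscorableTrial` when no signal qualifies.
    """
    timing = timing or ProtocolTiming()
    fs = rec.sample_rate
    m0, m1 = trial.movement_interval
    if trial.event == Event.GO_FORWARD:
        r0, r1 = trial.rest_interval
        # search beyond the transparent-mode window: the reach may peak
        # while position control holds the target posture
        search_end = min(rec.n_samples, m0 + int(round(timing.T_on * fs)))
        candidates = []
        for j in range(rec.joint_angles.shape[1]):
            baseline = float(np.mean(rec.joint_angles[r0:r1, j]))
            exc = np.abs(rec.joint_angles[m0:search_end, j] - baseline)
            peak = float(exc.max()) if exc.size else 0.0
            if peak < noise_floor_deg:
                continue
            idx = np.flatnonzero(exc >= peak_fraction * peak)
            if idx.size:
                candidates.append((m0 + int(idx[0])) / fs)
        if not candidates:
            raise UnscorableTrial(
                f"trial {trial.trial_index}: no joint excursion above "
                f"{noise_floor_deg} deg"
            )
        return min(candidates)
    # Go-backward: torque crossing after LED-off (= movement start)
    tau = timing.tau_thr
    seg = rec.torque_eFE[m0:m1]
    idx = np.flatnonzero(seg >= tau)
    if not idx.size:
        raise UnscorableTrial(
            f"trial {trial.trial_index}: torque never reaches {tau} N*m"
        )
    return (m0 + int(idx[0])) / fs


def score_detector(
    result: DetectionResult,
    trials: list[TrialSegmentation],
    sample_rate: float,
    t_pre: float = 0.5,
    t_post: float = 1.0,
    rest_labels: np.ndarray | None = None,
    detector_name: str = "",
) -> PerformanceReport:
    """Score one detection stream against reference-onset trials.

    A trial is a true positive when at least one detected onset falls in
    ``[t0 - t_pre, t0 + t_post]``; its latency is the first qualifying
    detection minus ``t0``.  Specificity is counted per feature step
    over rest-phase steps: a rest step labeled movement is a false
    positive.  Rest steps are taken from ``rest_labels`` (0 = rest at
    that step, anything else ignored) when given, else from the trials'
    rest intervals.
    """
    scorable = [t for t in trials if t.t0_reference is not None]
    if not scorable:
        raise ValueError("no scorable trials (t0_reference missing everywhere)")
    events = {t.event for t in scorable}
    if len(events) != 1:
        raise ValueError("trials must all belong to one event")
    event = events.pop()

    TP = 0
    latencies = []
    for tr in scorable:
        t0 = tr.t0_reference
        hits = result.onsets[
            (result.onsets >= t0 - t_pre) & (result.onsets <= t0 + t_post)
        ]
        if hits.size:
            TP += 1
            latencies.append(float(hits[0]) - t0)
    FN = len(scorable) - TP

    if rest_labels is not None:
        rest_mask = np.asarray(rest_labels) == 0
    else:
        rest_mask = np.zeros(result.times.size, dtype=bool)
        for tr in scorable:
            r0, r1 = tr.rest_interval
            rest_mask |= (result.times >= r0 / sample_rate) & (
                result.times < r1 / sample_rate
            )
    rest_steps = result.labels[rest_mask]
    FP = int(rest_steps.sum())
    TN = int(rest_steps.size - FP)
    return PerformanceReport(
        event=event, detector=detector_name or result.config.detector_type.value,
        TP=TP, FN=FN, TN=TN, FP=FP, latencies=np.asarray(latencies),
    )


# ---------------------------------------------------------------------------
# Training and cross-validation
# ---------------------------------------------------------------------------

def train_models(
    features_by_muscle: dict[str, FeatureSeries],
    trials: list[TrialSegmentation],
    sample_rate: float,
    feature_names: tuple[str, ...],
    muscles: tuple[str, ...] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> dict[tuple[str, str], GmmParams]:
    """Fit one two-component mixture per (muscle, feature) for one event.

    Training pools the feature samples of the event's rest and movement
    intervals across trials; the fit is unsupervised (EM discovers the
    two phases from the pooled marginal).
    """
    muscles = muscles or tuple(features_by_muscle)
    mask = None
    models: dict[tuple[str, str], GmmParams] = {}
    for muscle in muscles:
        fs_series = features_by_muscle[muscle]
        if mask is None:
            times = fs_series.times
            mask = np.zeros(times.size, dtype=bool)
            for tr in trials:
                for (a, b) in (tr.rest_interval, tr.movement_interval):
                    mask |= (times >= a / sample_rate) & (times < b / sample_rate)
        for feat in feature_names:
            samples = fs_series.column(feat)[mask]
            models[(muscle, feat)] = em_fit(samples, tol=tol, max_iter=max_iter).params
    return models


@dataclass
class CrossValResult:
    """Per-rotation reports plus pooled summary statistics."""

    reports: list[PerformanceReport]
    event: Event

    @property
    def sensitivity(self) -> float:
        return float(np.mean([r.sensitivity for r in self.reports]))

    @property
    def specificity(self) -> float:
        return float(np.mean([r.specificity for r in self.reports]))

    @property
    def latency_median(self) -> float:
        lats = np.concatenate([r.latencies for r in self.reports]) if self.reports else np.zeros(0)
        return float(np.median(lats)) if lats.size else float("nan")

    def pooled(self) -> PerformanceReport:
        return PerformanceReport(
            event=self.event,
            detector=self.reports[0].detector if self.reports else "",
            TP=sum(r.TP for r in self.reports),
            FN=sum(r.FN for r in self.reports),
            TN=sum(r.TN for r in self.reports),
            FP=sum(r.FP for r in self.reports),
            latencies=np.concatenate([r.latencies for r in self.reports])
            if self.reports else np.zeros(0),
        )


def _prepare_session(rec, timing, spec, feature_names, event, ground_truth=None):
    """Segment, featurize and reference-annotate one session."""
    feats = feature_matrix(rec, spec, names=feature_names)
    trials = [t for t in segment_trials(rec, timing, drop_truncated=True)
              if t.event == event]
    scored = []
    for tr in trials:
        try:
            tr.t0_reference = reference_onset(rec, tr, timing)
            scored.append(tr)
        except UnscorableTrial:
            continue
    times = next(iter(feats.values())).times
    rest_labels = None
    if ground_truth is not None:
        rest_labels = ground_truth.phase_labels(times, event)
    return feats, scored, rest_labels


def session_cross_validation(
    sessions: list[Recording],
    config: DetectorConfig,
    event: Event,
    timing: ProtocolTiming | None = None,
    spec: WindowSpec | None = None,
    L: int = 1000,
    t_pre: float = 0.5,
    t_post: float = 1.0,
    ground_truths: list | None = None,
) -> CrossValResult:
    """Session-wise rotation: train on each session, test on the rest.

    Each session in turn provides the EM training data; the resulting
    models are run (with sequential adaptation) over every other
    session, and the outcome measures are averaged over rotations.
    Sessions without scorable trials are excluded with a warning.
    """
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions for cross-validation")
    timing = timing or ProtocolTiming()
    spec = spec or WindowSpec()
    muscles = config.muscles or None
    feature_names = config.features

    prepared = []
    for i, rec in enumerate(sessions):
        gt = ground_truths[i] if ground_truths is not None else None
        prepared.append(_prepare_session(rec, timing, spec, feature_names, event, gt))

    from .detectors import DetectorType, combine_votes
    from .gmm import classify_streams

    muscles_used = config.muscles if config.muscles else tuple(prepared[0][0].keys())
    if config.detector_type == DetectorType.TYPE2_INFO:
        muscles_used = muscles_used[: config.subset_size]

    reports: list[PerformanceReport] = []
    for i_train, rec_train in enumerate(sessions):
        feats_train, trials_train, _ = prepared[i_train]
        if not trials_train:
            import warnings
            warnings.warn(f"session {i_train} has no scorable trials; skipped")
            continue
        models = train_models(
            feats_train, trials_train, rec_train.sample_rate,
            feature_names, muscles=config.muscles or None,
        )
        # batch every test session of this rotation (grouped by length)
        # into one adaptive-classification pass: streams are independent,
        # so batching changes nothing but the wall time
        tests = [i for i in range(len(sessions))
                 if i != i_train and prepared[i][1]]
        by_len: dict[int, list[int]] = {}
        for i in tests:
            n_steps = next(iter(prepared[i][0].values())).n_steps
            by_len.setdefault(n_steps, []).append(i)
        for group in by_len.values():
            cols, inits = [], []
            for i in group:
                feats_test = prepared[i][0]
                for m in muscles_used:
                    fs_ = feats_test[m]
                    for f in feature_names:
                        cols.append(fs_.column(f))
                        inits.append(models[(m, f)])
            X = np.column_stack(cols)
            res = classify_streams(X, inits, L=L)
            lab = res.labels if res.labels.ndim == 2 else res.labels[:, None]
            k_per = len(muscles_used) * len(feature_names)
            for gi, i in enumerate(group):
                feats_test, trials_test, rest_labels = prepared[i]
                times = next(iter(feats_test.values())).times
                sub = lab[:, gi * k_per:(gi + 1) * k_per]
                result = combine_votes(sub, times, muscles_used, config)
                reports.append(
                    score_detector(
                        result, trials_test, sessions[i].sample_rate,
                        t_pre=t_pre, t_post=t_post, rest_labels=rest_labels,
                        detector_name=config.detector_type.value,
                    )
                )
    return CrossValResult(reports=reports, event=event)


def subject_holdout_validation(
    subjects: dict[str, list[Recording]],
    config: DetectorConfig,
    event: Event,
    timing: ProtocolTiming | None = None,
    spec: WindowSpec | None = None,
    L: int = 1000,
    t_pre: float = 0.5,
    t_post: float = 1.0,
    ground_truths: dict[str, list] | None = None,
) -> dict[str, CrossValResult]:
    """Leave-one-subject-out rotation (subject-independent evaluation).

    For each held-out subject, models are trained on the pooled feature
    samples of the first session of every *other* subject and tested on
    all of the held-out subject's sessions.  Returns one result per
    held-out subject.
    """
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for a subject holdout")
    timing = timing or ProtocolTiming()
    spec = spec or WindowSpec()
    feature_names = config.features
    out: dict[str, CrossValResult] = {}
    for held_out in subjects:
        pooled: dict[tuple[str, str], list[np.ndarray]] = {}
        for other, recs in subjects.items():
            if other == held_out:
                continue
            rec = recs[0]
            feats, trials, _ = _prepare_session(
                rec, timing, spec, feature_names, event)
            mask = None
            for muscle, fs_series in feats.items():
                if config.muscles and muscle not in config.muscles:
                    continue
                if mask is None:
                    times = fs_series.times
                    mask = np.zeros(times.size, dtype=bool)
                    for tr in trials:
                        for (a, b) in (tr.rest_interval, tr.movement_interval):
                            mask |= (times >= a / rec.sample_rate) & (
                                times < b / rec.sample_rate)
                for feat in feature_names:
                    pooled.setdefault((muscle, feat), []).append(
                        fs_series.column(feat)[mask])
        models = {k: em_fit(np.concatenate(v)).params for k, v in pooled.items()}
        reports = []
        for i, rec in enumerate(subjects[held_out]):
            gt = (ground_truths or {}).get(held_out)
            gt_i = gt[i] if gt is not None else None
            feats, trials, rest_labels = _prepare_session(
                rec, timing, spec, feature_names, event, gt_i)
            if not trials:
                continue
            result = run_detector(feats, models, config, L=L)
            reports.append(score_detector(
                result, trials, rec.sample_rate, t_pre=t_pre, t_post=t_post,
                rest_labels=rest_labels,
                detector_name=config.detector_type.value))
        out[held_out] = CrossValResult(reports=reports, event=event)
    return out


def correlate_info_performance(
    performance: np.ndarray, info_by_feature: dict[str, np.ndarray]
) -> dict[str, tuple[float, float]]:
    """Pearson r (and p) between detector performance and feature information.

    ``performance`` holds the per-unit product sensitivity x specificity;
    each entry of ``info_by_feature`` holds that feature's information
    content for the same units in the same order.
    """
    perf = np.asarray(performance, dtype=float)
    if perf.size < 3:
        raise ValueError("need at least 3 paired observations")
    out = {}
    for name, info in info_by_feature.items():
        info = np.asarray(info, dtype=float)
        if info.size != perf.size:
            raise ValueError(f"feature {name!r}: unpaired observations")
        r, p = stats.pearsonr(perf, info)
        out[name] = (float(r), float(p))
    return out
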