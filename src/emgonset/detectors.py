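"""Majority-voting onset detectors.

A **Type 1** detector watches a single muscle: one adaptive mixture
model per feature classifies each windowed sample as rest or movement,
and the per-feature votes are combined by majority voting (the decision
is *rest* only when at least ``floor(M/2) + 1`` of the M features vote
rest, so ties go to movement — the safety-relevant class for triggering
assistance).

A **Type 2** detector applies the same voting rule across the Type 1
outputs of several muscles (all seven, or — *info-based* — only the
``P`` most informative muscles for the event, default ``P = 3``, the
smallest odd panel that supports a strict majority).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .features import OPERATING_SET, FeatureSeries
from .gmm import GmmParams, classify_streams

__all__ = [
    "DetectionResult",
    "DetectorConfig",
    "DetectorType",
    "majority_vote",
    "run_detector",
    "type1_vote",
    "type2_vote",
]


class DetectorType(str, Enum):
    TYPE1 = "type1"
    TYPE2 = "type2"
    TYPE2_INFO = "type2-info"


@dataclass(frozen=True)
class DetectorConfig:
    """What signals feed the detector and how votes are combined.

    ``muscles`` lists the voting muscles (exactly one for Type 1;
    for the info-based Type 2 it should be the top-``subset_size``
    muscles ranked by information content).  ``features`` are the
    per-muscle voting features.  ``debounce`` requires that many
    consecutive movement steps before an onset is declared.
    """

    detector_type: DetectorType = DetectorType.TYPE2_INFO
    muscles: tuple[str, ...] = ()
    features: tuple[str, ...] = OPERATING_SET
    subset_size: int = 3
    debounce: int = 1

    def __post_init__(self) -> None:
        if self.detector_type == DetectorType.TYPE1 and len(self.muscles) != 1:
            raise ValueError("Type 1 detector requires exactly one muscle")
        if self.detector_type == DetectorType.TYPE2_INFO and self.muscles:
            if self.subset_size > len(self.muscles):
                raise ValueError("subset_size cannot exceed the muscle panel")
        if self.debounce < 1:
            raise ValueError("debounce must be >= 1")
        if not self.features:
            raise ValueError("at least one voting feature is required")


@dataclass
class DetectionResult:
    """Per-step decisions of a detector over one session.

    ``labels`` is the binary rest/movement stream at the feature update
    rate, ``times`` its timestamps, ``onsets`` the detected onset times
    (rest-to-movement transitions surviving debounce), and
    ``theta_traces`` maps ``(muscle, feature)`` to the adaptive
    threshold trace.
    """

    labels: np.ndarray
    times: np.ndarray
    onsets: np.ndarray
    theta_traces: dict[tuple[str, str], np.ndarray]
    config: DetectorConfig
    muscle_labels: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Voting
# ---------------------------------------------------------------------------

def majority_vote(votes: np.ndarray) -> np.ndarray:
    """Combine binary votes (1 = movement) along the last axis.

    The decision is rest (0) only when rest votes reach a strict
    majority, ``floor(M/2) + 1``; otherwise movement.  Works on a single
    vote vector or a [step x voter] matrix.
    """
    votes = np.asarray(votes)
    if votes.size == 0 or votes.shape[-1] == 0:
        raise ValueError("empty vote vector")
    m = votes.shape[-1]
    movement_quorum = m - (m // 2 + 1) + 1  # rest wins iff rest votes >= m//2 + 1
    return (votes.sum(axis=-1) >= movement_quorum).astype(np.uint8)


def type1_vote(feature_labels: np.ndarray) -> np.ndarray:
    """Majority vote across the features of one muscle."""
    return majority_vote(feature_labels)


def type2_vote(channel_labels: np.ndarray) -> np.ndarray:
    """Majority vote across Type 1 sub-detector outputs."""
    return majority_vote(channel_labels)


def extract_onsets(
    labels: np.ndarray, times: np.ndarray, debounce: int = 1
) -> np.ndarray:
    """Times of rest-to-movement transitions surviving debounce.

    A transition at step *t* counts only if steps ``t .. t+debounce-1``
    are all movement.  A movement-labeled first step is not an onset
    (there is no observed transition).
    """
    lab = np.asarray(labels).astype(bool)
    if lab.size == 0:
        return np.zeros(0)
    rising = np.flatnonzero(lab[1:] & ~lab[:-1]) + 1
    if debounce > 1:
        keep = [
            i for i in rising
            if i + debounce <= lab.size and lab[i:i + debounce].all()
        ]
        rising = np.asarray(keep, dtype=int)
    return times[rising]


# ---------------------------------------------------------------------------
# Full detector
# ---------------------------------------------------------------------------

def run_detector(
    features_by_muscle: dict[str, FeatureSeries],
    models: dict[tuple[str, str], GmmParams],
    config: DetectorConfig,
    L: int = 1000,
) -> DetectionResult:
    """Run a configured detector over one session's feature series.

    Every ``(muscle, feature)`` stream named by the configuration is
    classified with its own adaptive mixture model (one batched pass),
    per-muscle feature votes produce Type 1 decisions and, for Type 2
    variants, a second vote across muscles produces the final stream.
    Missing models raise a configuration error naming the pair.
    """
    muscles = config.muscles or tuple(features_by_muscle)
    if config.detector_type == DetectorType.TYPE2_INFO:
        muscles = muscles[: config.subset_size]
    streams: list[np.ndarray] = []
    inits: list[GmmParams] = []
    keys: list[tuple[str, str]] = []
    times = None
    for muscle in muscles:
        if muscle not in features_by_muscle:
            raise KeyError(f"no feature series for muscle {muscle!r}")
        fs = features_by_muscle[muscle]
        if times is None:
            times = fs.times
        for feat in config.features:
            if (muscle, feat) not in models:
                raise KeyError(f"missing trained model for (muscle={muscle!r}, feature={feat!r})")
            streams.append(fs.column(feat))
            inits.append(models[(muscle, feat)])
            keys.append((muscle, feat))
    assert times is not None
    X = np.column_stack(streams)
    res = classify_streams(X, inits, L=L)
    lab = res.labels if res.labels.ndim == 2 else res.labels[:, None]
    th = res.theta_trace if res.theta_trace.ndim == 2 else res.theta_trace[:, None]
    theta_traces = {k: th[:, i] for i, k in enumerate(keys)}
    return combine_votes(lab, times, muscles, config, theta_traces)


def combine_votes(
    feature_labels: np.ndarray,
    times: np.ndarray,
    muscles: tuple[str, ...],
    config: DetectorConfig,
    theta_traces: dict[tuple[str, str], np.ndarray] | None = None,
) -> DetectionResult:
    """Fold per-(muscle, feature) label streams into a final decision.

    ``feature_labels`` is [step x (muscle-major, feature-minor)] in the
    order implied by ``muscles`` and ``config.features``.
    """
    n_feat = len(config.features)
    lab3 = feature_labels.reshape(feature_labels.shape[0], len(muscles), n_feat)
    muscle_labels = {m: type1_vote(lab3[:, i, :]) for i, m in enumerate(muscles)}
    if config.detector_type == DetectorType.TYPE1:
        final = muscle_labels[muscles[0]]
    else:
        stacked = np.column_stack([muscle_labels[m] for m in muscles])
        final = type2_vote(stacked)
    onsets = extract_onsets(final, times, config.debounce)
    return DetectionResult(
        labels=final, times=times, onsets=onsets,
        theta_traces=theta_traces or {}, config=config,
        muscle_labels=muscle_labels,
    )
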