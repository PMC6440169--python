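"""Session I/O, offline preprocessing and trial segmentation.

A *session* is a synchronized multichannel recording of a seated reaching
protocol: seven surface-EMG channels, four exoskeleton joint angles, the
elbow flexion/extension interaction torque, an LED cue state and the
robot control-mode state, all sampled on a common 1 kHz time base.

Each 12 s trial contains two scored rest-to-movement transitions:

* **Go-forward** — the LED turns on, the robot switches to transparent
  (zero-torque) mode and the subject reaches toward the target;
* **Go-backward** — the LED turns off and the subject pushes against the
  position-held elbow until the interaction torque crosses a threshold,
  then returns to rest.

Sessions are stored as plain CSV with a ``#``-prefixed metadata header.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "CHANNEL_NAMES",
    "JOINT_NAMES",
    "Event",
    "FormatError",
    "ProtocolTiming",
    "Recording",
    "TrialSegmentation",
    "preprocess",
    "read_recording",
    "segment_trials",
    "write_recording",
]

#: Canonical muscle order of the seven-channel montage (right shoulder,
#: arm and forearm).
CHANNEL_NAMES = (
    "Trapezius",
    "AnteriorDeltoid",
    "PosteriorDeltoid",
    "Biceps",
    "Triceps",
    "FlexorCarpiUlnaris",
    "ExtensorCarpiUlnaris",
)

#: Active exoskeleton joints: shoulder adduction/abduction,
#: flexion/extension, internal/external rotation; elbow flexion/extension.
JOINT_NAMES = ("sAA", "sFE", "sIE", "eFE")

TRANSPARENT_MODE = 0
POSITION_MODE = 1


class FormatError(ValueError):
    """Raised for malformed session files or inconsistent recordings."""


class Event(str, Enum):
    """The two scored rest-to-movement transitions."""

    GO_FORWARD = "GoForward"
    GO_BACKWARD = "GoBackward"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ProtocolTiming:
    """Timing constants of one reaching trial.

    Defaults follow the experimental protocol: 12 s trials with the LED
    on for 6 s (2.5 s transparent mode, then 3.5 s position control) and
    off for 6 s; a 2 N·m elbow-torque threshold arms the return movement.
    """

    T: float = 12.0
    T_on: float = 6.0
    T_off: float = 6.0
    T_r1: float = 2.5
    T_r2: float = 3.5
    tau_thr: float = 2.0

    def __post_init__(self) -> None:
        vals = (self.T, self.T_on, self.T_off, self.T_r1, self.T_r2)
        if any(v <= 0 for v in vals):
            raise ValueError("all protocol durations must be strictly positive")
        if abs(self.T_r1 + self.T_r2 - self.T_on) > 1e-9:
            raise ValueError("T_r1 + T_r2 must equal T_on")
        if abs(self.T_on + self.T_off - self.T) > 1e-9:
            raise ValueError("T_on + T_off must equal T")


@dataclass
class Recording:
    """One synchronized session.

    All arrays share the first dimension (sample count) and the sample
    rate.  EMG is stored column-per-muscle in volts, joint angles in
    degrees, torque in N·m.  ``led_state`` uses 0 = off and 1..3 for the
    west/center/east targets; ``control_mode`` is 0 = transparent,
    1 = position control.
    """

    sample_rate: float
    emg: np.ndarray
    channel_names: tuple[str, ...]
    joint_angles: np.ndarray
    torque_eFE: np.ndarray
    led_state: np.ndarray
    control_mode: np.ndarray
    session_id: str = "S0"
    subject_id: str = "subj0"
    joint_names: tuple[str, ...] = JOINT_NAMES

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        if self.emg.ndim != 2:
            raise FormatError("emg must be a 2-D array [samples, channels]")
        self.joint_angles = np.asarray(self.joint_angles, dtype=float)
        self.torque_eFE = np.asarray(self.torque_eFE, dtype=float)
        self.led_state = np.asarray(self.led_state, dtype=int)
        self.control_mode = np.asarray(self.control_mode, dtype=int)
        self.channel_names = tuple(self.channel_names)

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        """Return one EMG channel by muscle name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; have {list(self.channel_names)}"
            ) from None
        return self.emg[:, idx]

    def validate(self, strict: bool = True) -> None:
        """Check the shared-length / shared-rate invariants.

        With ``strict`` the montage must be exactly the seven expected
        muscles; otherwise any duplicate-free channel list is accepted.
        """
        n = self.n_samples
        if self.sample_rate <= 0:
            raise FormatError("sample_rate must be positive")
        if len(self.channel_names) != self.emg.shape[1]:
            raise FormatError("channel_names length must match emg columns")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise FormatError("duplicate channel names")
        if strict and self.channel_names != CHANNEL_NAMES:
            raise FormatError(
                f"strict mode expects the canonical 7-muscle montage {CHANNEL_NAMES}"
            )
        for label, arr, dim in (
            ("joint_angles", self.joint_angles, 2),
            ("torque_eFE", self.torque_eFE, 1),
            ("led_state", self.led_state, 1),
            ("control_mode", self.control_mode, 1),
        ):
            if arr.ndim != dim:
                raise FormatError(f"{label} must be {dim}-D")
            if arr.shape[0] != n:
                raise FormatError(f"{label} length {arr.shape[0]} != emg length {n}")
        if self.joint_angles.shape[1] != len(self.joint_names):
            raise FormatError("joint_angles must have one column per joint name")
        if not np.isfinite(self.emg).all():
            raise FormatError("emg contains non-finite values")

    def preprocessed(self, causal: bool = False) -> "Recording":
        """Return a copy with every EMG channel run through :func:`preprocess`."""
        emg = np.column_stack(
            [preprocess(self.emg[:, c], self.sample_rate, causal=causal)
             for c in range(self.emg.shape[1])]
        )
        return replace(self, emg=emg)


@dataclass
class TrialSegmentation:
    """Rest/movement phase intervals of one event within one trial.

    Intervals are half-open ``[start, end)`` in 0-based sample indices.
    ``t0_reference`` (seconds) is the kinematic or torque reference onset
    filled in by the evaluation stage.
    """

    trial_index: int
    event: Event
    rest_interval: tuple[int, int]
    movement_interval: tuple[int, int]
    t0_reference: float | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        r0, r1 = self.rest_interval
        m0, m1 = self.movement_interval
        if not (r0 < r1 and m0 < m1):
            raise ValueError("intervals must be non-empty")
        if r1 > m0:
            raise ValueError("rest interval must precede the movement interval")


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = (
    ["time_s"]
    + [f"emg_{name}" for name in CHANNEL_NAMES]
    + [f"angle_{j}_deg" for j in JOINT_NAMES]
    + ["torque_eFE_Nm", "led_state", "control_mode"]
)


def read_recording(path: str | Path, strict: bool = True) -> Recording:
    """Read a session CSV written in the package dialect.

    The file carries ``# key: value`` comment lines for ``subject_id``,
    ``session_id`` and ``sample_rate``, then a comma-separated table with
    one row per sample.  Raises :class:`FormatError` for a missing
    required column or a non-monotone time column.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line.lstrip("#").partition(":")
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing and strict:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if "time_s" not in df.columns:
        raise FormatError("missing required column(s): time_s")
    t = df["time_s"].to_numpy(float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise FormatError("time_s column is not strictly increasing")
    sample_rate = float(meta.get("sample_rate", 0.0))
    if sample_rate <= 0:
        if len(t) > 1:
            sample_rate = 1.0 / float(np.median(np.diff(t)))
        else:
            sample_rate = 1000.0
    channels = [c[len("emg_"):] for c in df.columns if c.startswith("emg_")]
    emg = df[[f"emg_{c}" for c in channels]].to_numpy(float)
    joints = [c[len("angle_"):-len("_deg")] for c in df.columns if c.startswith("angle_")]
    if joints:
        angles = df[[f"angle_{j}_deg" for j in joints]].to_numpy(float)
    else:
        angles = np.zeros((len(df), len(JOINT_NAMES)))
        joints = list(JOINT_NAMES)
    torque = (
        df["torque_eFE_Nm"].to_numpy(float)
        if "torque_eFE_Nm" in df.columns
        else np.zeros(len(df))
    )
    led = (
        df["led_state"].to_numpy(int) if "led_state" in df.columns else np.zeros(len(df), int)
    )
    mode = (
        df["control_mode"].to_numpy(int)
        if "control_mode" in df.columns
        else np.zeros(len(df), int)
    )
    rec = Recording(
        sample_rate=sample_rate,
        emg=emg,
        channel_names=tuple(channels),
        joint_angles=angles,
        joint_names=tuple(joints),
        torque_eFE=torque,
        led_state=led,
        control_mode=mode,
        session_id=meta.get("session_id", "S0"),
        subject_id=meta.get("subject_id", "subj0"),
    )
    rec.validate(strict=strict)
    return rec


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a session in the CSV dialect read by :func:`read_recording`."""
    rec.validate(strict=False)
    path = Path(path)
    cols: dict[str, np.ndarray] = {"time_s": rec.times}
    for i, name in enumerate(rec.channel_names):
        cols[f"emg_{name}"] = rec.emg[:, i]
    for j, name in enumerate(rec.joint_names):
        cols[f"angle_{name}_deg"] = rec.joint_angles[:, j]
    cols["torque_eFE_Nm"] = rec.torque_eFE
    cols["led_state"] = rec.led_state
    cols["control_mode"] = rec.control_mode
    buf = _stdio.StringIO()
    pd.DataFrame(cols).to_csv(buf, index=False, float_format="%.10g")
    header = (
        f"# subject_id: {rec.subject_id}\n"
        f"# session_id: {rec.session_id}\n"
        f"# sample_rate: {rec.sample_rate:g}\n"
    )
    path.write_text(header + buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    x: np.ndarray,
    sample_rate: float,
    highpass_hz: float = 10.0,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
    causal: bool = False,
) -> np.ndarray:
    """High-pass then mains-notch filter one EMG channel.

    A 4th-order Butterworth high-pass at 10 Hz removes motion artefact
    and offset left after hardware band-pass filtering, and an IIR notch
    (Q = 30) suppresses residual 50 Hz powerline interference.  The
    default is zero-phase (forward-backward) application so that filter
    group delay cannot bias detection-latency estimates; ``causal=True``
    applies both filters forward-only, emulating an online pipeline.
    """
    x = np.asarray(x, dtype=float)
    if sample_rate <= 100:
        raise ValueError("sample_rate must exceed 100 Hz")
    sos = signal.butter(4, highpass_hz, btype="highpass", fs=sample_rate, output="sos")
    b_notch, a_notch = signal.iirnotch(notch_hz, notch_q, fs=sample_rate)
    # forward-backward filtering needs padding: 3 * max(len(a), len(b)) per
    # stage; require the series comfortably longer instead of silently
    # truncating the padding.
    min_len = 3 * (2 * 4 + 1) + 1
    if x.size < min_len:
        raise ValueError(
            f"series of length {x.size} is too short to filter "
            f"(need at least {min_len} samples)"
        )
    if causal:
        y = signal.sosfilt(sos, x)
        y = signal.lfilter(b_notch, a_notch, y)
    else:
        y = signal.sosfiltfilt(sos, x)
        # the notch rings for ~Q cycles; pad accordingly or edge
        # transients leak through the stop band
        ring = int(notch_q * sample_rate / notch_hz)
        y = signal.filtfilt(b_notch, a_notch, y, padlen=min(ring, x.size - 1))
    return y


# ---------------------------------------------------------------------------
# Trial segmentation
# ---------------------------------------------------------------------------

def segment_trials(
    rec: Recording,
    timing: ProtocolTiming | None = None,
    drop_truncated: bool = False,
) -> list[TrialSegmentation]:
    """Split a session into per-trial rest/movement phase intervals.

    For every LED off-to-on transition two segmentations are emitted:

    * Go-forward: rest is the tail of the preceding LED-off period (the
      subject back at rest), movement runs from LED-on until position
      control engages (``T_r1`` after the cue);
    * Go-backward: rest is the position-held window at the target,
      movement runs from LED-off over the first half of the off period
      (covering the torque build-up and the return).

    Trials whose LED-on episode is shorter than ``T_r1`` (e.g. a
    truncated final trial) are flagged ``truncated`` and optionally
    dropped.
    """
    timing = timing or ProtocolTiming()
    fs = rec.sample_rate
    led_on = (rec.led_state > 0).astype(int)
    d = np.diff(led_on)
    onsets = np.flatnonzero(d == 1) + 1
    offsets = np.flatnonzero(d == -1) + 1
    if onsets.size == 0:
        raise FormatError("led_state exhibits no off-to-on transition")

    n = rec.n_samples
    r1 = int(round(timing.T_r1 * fs))
    t_on_len = int(round(timing.T_on * fs))
    rest_len = int(round(timing.T_off * fs / 2))
    ret_len = int(round(timing.T_off * fs / 2))

    out: list[TrialSegmentation] = []
    for k, i_on in enumerate(onsets):
        i_off_candidates = offsets[offsets > i_on]
        i_off = int(i_off_candidates[0]) if i_off_candidates.size else n
        truncated = (i_off - i_on) < t_on_len - 1

        # --- Go-forward -------------------------------------------------
        r_start = max(0, i_on - rest_len)
        m_end = min(i_on + r1, n)
        fw_trunc = truncated or m_end < i_on + r1
        if r_start < i_on and i_on < m_end:
            out.append(
                TrialSegmentation(
                    trial_index=k,
                    event=Event.GO_FORWARD,
                    rest_interval=(r_start, i_on),
                    movement_interval=(i_on, m_end),
                    truncated=fw_trunc,
                )
            )

        # --- Go-backward ------------------------------------------------
        hold_start = min(i_on + r1, n)
        hold_end = min(i_off, n)
        ret_end = min(i_off + ret_len, n)
        bw_trunc = truncated or ret_end < i_off + ret_len
        if hold_start < hold_end and hold_end < ret_end:
            out.append(
                TrialSegmentation(
                    trial_index=k,
                    event=Event.GO_BACKWARD,
                    rest_interval=(hold_start, hold_end),
                    movement_interval=(hold_end, ret_end),
                    truncated=bw_trunc,
                )
            )
    if drop_truncated:
        out = [s for s in out if not s.truncated]
    return out
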