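"""Protocol-faithful synthetic reaching sessions with ground truth.

The generator emulates the seated LED-cued reaching protocol: 12 s
trials (LED on 6 s, off 6 s), a transparent-mode reaction window, a
position-controlled hold at the target, and a torque-crossing return
initiation.  It produces everything a real session contains — seven EMG
channels, four joint angles, elbow torque, LED and control-mode
timelines — plus the ground truth no real recording has: the exact EMG
onset, kinematic onset and torque-crossing time of every trial, and
per-step rest/movement phase labels.

The EMG model is amplitude-modulated white Gaussian noise: channel
``c`` is ``sigma_c(t) * n(t)`` with

    sigma_c(t) = sigma_rest_c * d(t) * (1 + (gain_c - 1) * env(t))

where ``env`` is a burst envelope rising at the true EMG onset,
``gain_c`` the per-muscle activation gain for the event, and ``d(t)``
an optional slow drift of the background level (for exercising
threshold adaptation).  This is the standard interference-pattern
surrogate for surface EMG: it reproduces the amplitude statistics the
time-domain features and the mixture model consume, without
motor-unit-level structure.

Joint angles follow minimum-jerk profiles beginning one
electromechanical delay after the EMG onset; the return torque is a
linear ramp crossing the 2 N·m threshold at a recorded time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CHANNEL_NAMES,
    JOINT_NAMES,
    POSITION_MODE,
    TRANSPARENT_MODE,
    Event,
    ProtocolTiming,
    Recording,
)

__all__ = ["GroundTruth", "SynthConfig", "simulate_session", "simulate_subject"]

#: Per-muscle activation gains (rest-noise multipliers) per event.  The
#: reach is driven mainly by the deltoids and biceps; the return is
#: initiated by elbow/wrist flexion against the held exoskeleton, seen
#: most strongly on the extensor carpi ulnaris and biceps.
DEFAULT_GAINS_FORWARD = {
    "Trapezius": 1.6,
    "AnteriorDeltoid": 4.0,
    "PosteriorDeltoid": 3.0,
    "Biceps": 2.5,
    "Triceps": 1.5,
    "FlexorCarpiUlnaris": 1.0,
    "ExtensorCarpiUlnaris": 1.0,
}
DEFAULT_GAINS_BACKWARD = {
    "Trapezius": 1.0,
    "AnteriorDeltoid": 1.3,
    "PosteriorDeltoid": 1.0,
    "Biceps": 2.5,
    "Triceps": 1.6,
    "FlexorCarpiUlnaris": 1.2,
    "ExtensorCarpiUlnaris": 3.5,
}

#: Resting joint posture (degrees) and reach excursions per joint.
_REST_ANGLES = np.array([5.0, 10.0, 0.0, 80.0])
_REACH_DELTAS = np.array([8.0, 35.0, 6.0, -30.0])


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of one synthetic subject.

    Defaults mirror the experimental protocol: 7 sessions of 24 reaching
    trials, 1 kHz sampling, ~300 ms reaction times and an 80 ms
    electromechanical delay between EMG onset and overt motion.
    ``drift`` linearly scales the background noise level across a
    session (0 = stationary); ``mains_amp`` adds a 50 Hz interference
    sinusoid of the given amplitude (volts).
    """

    timing: ProtocolTiming = field(default_factory=ProtocolTiming)
    sample_rate: float = 1000.0
    n_trials: int = 24
    n_sessions: int = 7
    reaction_mean: float = 0.30
    reaction_sd: float = 0.05
    reaction_floor: float = 0.10
    emd: float = 0.08
    sigma_rest: float = 20e-6
    gains_forward: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GAINS_FORWARD))
    gains_backward: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GAINS_BACKWARD))
    envelope: str = "raised_cosine"
    rise_time: float = 0.15
    move_duration: float = 1.2
    torque_slope: float = 10.0
    drift: float = 0.0
    mains_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_sessions < 1:
            raise ValueError("n_trials and n_sessions must be >= 1")
        if self.envelope not in ("raised_cosine", "trapezoid"):
            raise ValueError("envelope must be 'raised_cosine' or 'trapezoid'")
        if self.reaction_floor <= 0 or self.emd < 0:
            raise ValueError("reaction_floor must be > 0 and emd >= 0")
        if self.sigma_rest <= 0 or self.torque_slope <= 0:
            raise ValueError("sigma_rest and torque_slope must be positive")
        for gains in (self.gains_forward, self.gains_backward):
            missing = set(CHANNEL_NAMES) - set(gains)
            if missing:
                raise ValueError(f"missing gains for muscles: {sorted(missing)}")
            if any(g < 1.0 for g in gains.values()):
                raise ValueError("activation gains must be >= 1")


@dataclass
class GroundTruth:
    """Per-trial true onset times (seconds) and phase-label machinery."""

    timing: ProtocolTiming
    led_on_times: np.ndarray        # cue time per trial
    t_emg_forward: np.ndarray       # true EMG burst onset, Go-forward
    t_kin_forward: np.ndarray       # true kinematic onset (EMG + EMD)
    t_emg_backward: np.ndarray      # true EMG burst onset, Go-backward
    t_torque_cross: np.ndarray      # torque-threshold crossing time

    @property
    def n_trials(self) -> int:
        return self.led_on_times.size

    def phase_labels(self, times: np.ndarray, event: Event) -> np.ndarray:
        """Rest(0)/movement(1) labels at arbitrary timestamps; -1 = unscored.

        Go-forward: rest over the pre-cue window, movement from the true
        EMG onset until position control engages; the reaction gap
        between cue and EMG onset is unscored.  Go-backward: rest over
        the position-held hold, movement from the true EMG onset through
        the return.
        """
        times = np.asarray(times, dtype=float)
        lab = np.full(times.size, -1, dtype=np.int8)
        tm = self.timing
        for k in range(self.n_trials):
            t_on = self.led_on_times[k]
            if event == Event.GO_FORWARD:
                rest = (t_on - tm.T_off / 2, t_on)
                mov = (self.t_emg_forward[k], t_on + tm.T_r1)
            else:
                t_off = t_on + tm.T_on
                rest = (t_on + tm.T_r1, t_off)
                mov = (self.t_emg_backward[k], t_off + tm.T_off / 2)
            lab[(times >= rest[0]) & (times < rest[1])] = 0
            lab[(times >= mov[0]) & (times < mov[1])] = 1
        return lab

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(self.n_trials):
            rows.append({"trial": k, "event": Event.GO_FORWARD.value,
                         "t_emg_onset_s": self.t_emg_forward[k],
                         "t_kin_onset_s": self.t_kin_forward[k],
                         "t_torque_cross_s": np.nan})
            rows.append({"trial": k, "event": Event.GO_BACKWARD.value,
                         "t_emg_onset_s": self.t_emg_backward[k],
                         "t_kin_onset_s": np.nan,
                         "t_torque_cross_s": self.t_torque_cross[k]})
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def _envelope(t: np.ndarray, start: float, plateau_end: float,
              rise: float, fall: float, kind: str) -> np.ndarray:
    """Burst envelope: 0 before ``start``, 1 on the plateau, smooth edges."""
    env = np.zeros_like(t)
    up = (t >= start) & (t < start + rise)
    if kind == "raised_cosine":
        env[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - start) / rise))
    else:
        env[up] = (t[up] - start) / rise
    env[(t >= start + rise) & (t < plateau_end)] = 1.0
    down = (t >= plateau_end) & (t < plateau_end + fall)
    if kind == "raised_cosine":
        env[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - plateau_end) / fall))
    else:
        env[down] = 1.0 - (t[down] - plateau_end) / fall
    return env


def _min_jerk(t: np.ndarray, start: float, duration: float) -> np.ndarray:
    """Normalized minimum-jerk position profile (0 before, 1 after)."""
    s = np.clip((t - start) / duration, 0.0, 1.0)
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      floor: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = out <= floor
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.maximum(out, floor)


def simulate_session(
    config: SynthConfig, session_index: int = 0, subject_id: str = "synth0"
) -> tuple[Recording, GroundTruth]:
    """Generate one session and its ground truth.

    Fully reproducible: the random stream is derived from
    ``(config.seed, session_index)``.  The session starts with one
    LED-off lead-in of ``T_off`` seconds so the first trial has a rest
    window, followed by ``n_trials`` trials of ``T`` seconds each.
    """
    tm = config.timing
    fs = config.sample_rate
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, session_index]))

    lead_in = tm.T_off
    total_t = lead_in + config.n_trials * tm.T
    n = int(round(total_t * fs))
    t = np.arange(n) / fs

    led = np.zeros(n, dtype=int)
    mode = np.zeros(n, dtype=int) + TRANSPARENT_MODE
    torque = np.zeros(n)
    angles = np.tile(_REST_ANGLES, (n, 1))

    led_on_times = lead_in + tm.T * np.arange(config.n_trials)
    targets = rng.integers(1, 4, size=config.n_trials)  # W/C/E codes 1..3
    react_fw = _truncated_normal(rng, config.reaction_mean, config.reaction_sd,
                                 config.reaction_floor, config.n_trials)
    react_bw = _truncated_normal(rng, config.reaction_mean, config.reaction_sd,
                                 config.reaction_floor, config.n_trials)

    t_emg_fw = led_on_times + react_fw
    t_kin_fw = t_emg_fw + config.emd
    t_off_times = led_on_times + tm.T_on
    t_emg_bw = t_off_times + react_bw
    # torque ramps one electromechanical delay after the return EMG onset
    t_ramp = t_emg_bw + config.emd
    t_cross = t_ramp + tm.tau_thr / config.torque_slope

    env_fw_total = np.zeros(n)
    env_bw_total = np.zeros(n)

    for k in range(config.n_trials):
        i_on = int(round(led_on_times[k] * fs))
        i_off = int(round(t_off_times[k] * fs))
        i_mode_on = int(round((led_on_times[k] + tm.T_r1) * fs))
        i_cross = int(round(t_cross[k] * fs))
        led[i_on:i_off] = targets[k]
        mode[i_mode_on:min(i_cross, n)] = POSITION_MODE

        # reach and return kinematics (minimum jerk per joint)
        dir_scale = {1: -1.0, 2: 0.35, 3: 1.0}[int(targets[k])]
        deltas = _REACH_DELTAS.copy()
        deltas[0] *= dir_scale  # shoulder ab/adduction depends on target side
        reach = _min_jerk(t, t_kin_fw[k], config.move_duration)
        ret = _min_jerk(t, t_cross[k], config.move_duration)
        angles += np.outer(reach - ret, deltas)

        # return torque: linear ramp to 2x threshold, then release
        ramp = np.clip((t - t_ramp[k]) * config.torque_slope, 0.0, 2 * tm.tau_thr)
        release = np.clip(1.0 - (t - t_cross[k] - 0.3) / 0.5, 0.0, 1.0)
        torque += ramp * release

        env_fw_total += _envelope(
            t, t_emg_fw[k], t_kin_fw[k] + config.move_duration,
            config.rise_time, 0.4, config.envelope)
        env_bw_total += _envelope(
            t, t_emg_bw[k], t_cross[k] + config.move_duration,
            config.rise_time, 0.4, config.envelope)

    env_fw_total = np.clip(env_fw_total, 0.0, 1.0)
    env_bw_total = np.clip(env_bw_total, 0.0, 1.0)

    drift_factor = 1.0 + config.drift * (t / total_t)
    emg = np.empty((n, len(CHANNEL_NAMES)))
    for c, name in enumerate(CHANNEL_NAMES):
        g_fw = config.gains_forward[name]
        g_bw = config.gains_backward[name]
        sigma = config.sigma_rest * drift_factor * (
            1.0 + (g_fw - 1.0) * env_fw_total + (g_bw - 1.0) * env_bw_total
        )
        emg[:, c] = sigma * rng.standard_normal(n)
        if config.mains_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            emg[:, c] += config.mains_amp * np.sin(2 * np.pi * 50.0 * t + phase)

    angles += rng.normal(0.0, 0.05, size=angles.shape)  # encoder noise, deg
    torque += rng.normal(0.0, 0.01, size=n)             # torque sensor noise

    rec = Recording(
        sample_rate=fs, emg=emg, channel_names=CHANNEL_NAMES,
        joint_angles=angles, joint_names=JOINT_NAMES, torque_eFE=torque,
        led_state=led, control_mode=mode,
        session_id=f"S{session_index}", subject_id=subject_id,
    )
    gt = GroundTruth(
        timing=tm, led_on_times=led_on_times,
        t_emg_forward=t_emg_fw, t_kin_forward=t_kin_fw,
        t_emg_backward=t_emg_bw, t_torque_cross=t_cross,
    )
    return rec, gt


def simulate_subject(config: SynthConfig, subject_id: str = "synth0"):
    """Generate all sessions of one synthetic subject (list of pairs)."""
    return [
        simulate_session(config, session_index=s, subject_id=subject_id)
        for s in range(config.n_sessions)
    ]
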