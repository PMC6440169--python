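"""Time-domain EMG features over sliding windows.

Fourteen amplitude-derived features are computed within a sliding window
(default 300 ms, updated every 10 ms).  All are standard time-domain
descriptors from the myoelectric-control literature:

====== =====================================================
IAV    integrated absolute value, sum |x_i|
MAV    mean absolute value, IAV / N
MMAV1  MAV with step weights (1 in the middle half, 0.5 at the ends)
MMAV2  MAV with ramped end weights (linear 0..1 over each end quarter)
SSI    simple square integral, sum x_i^2
VAR    variance about zero, SSI / (N - 1)
RMS    root mean square
WL     waveform length, sum |x_{i+1} - x_i|
LOG    log detector, exp(mean ln |x_i|)
ZC     zero crossings exceeding an amplitude threshold
SSC    slope-sign changes exceeding a threshold
WAMP   Willison amplitude, count |x_{i+1} - x_i| >= eps
AAC    average amplitude change, WL / N
DASDV  difference absolute standard deviation value
====== =====================================================

Counting features (ZC, SSC, WAMP) take a small amplitude threshold
``eps`` that rejects noise-level fluctuations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import Recording

__all__ = [
    "FEATURE_NAMES",
    "OPERATING_SET",
    "FeatureSeries",
    "WindowSpec",
    "compute_feature",
    "feature_matrix",
]

#: Floor used when taking logarithms of near-zero amplitudes (volts).
LOG_FLOOR = 1e-12

FEATURE_NAMES = (
    "IAV", "MAV", "MMAV1", "MMAV2", "SSI", "VAR", "RMS",
    "WL", "LOG", "ZC", "SSC", "WAMP", "AAC", "DASDV",
)

#: The subject-independent operating subset used by the onset detectors —
#: maximally informative about the rest/movement phase while minimally
#: redundant and maximally synergistic (see the infotheory module).
OPERATING_SET = ("IAV", "SSI", "WL", "LOG")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in milliseconds."""

    length_ms: float = 300.0
    step_ms: float = 10.0

    def in_samples(self, sample_rate: float) -> tuple[int, int]:
        """Convert to whole sample counts, validating divisibility."""
        w = self.length_ms * sample_rate / 1000.0
        s = self.step_ms * sample_rate / 1000.0
        if abs(w - round(w)) > 1e-9 or abs(s - round(s)) > 1e-9:
            raise ValueError(
                f"window {self.length_ms} ms / step {self.step_ms} ms do not "
                f"map to whole samples at {sample_rate} Hz"
            )
        w, s = int(round(w)), int(round(s))
        if s > w:
            raise ValueError("step must not exceed window length")
        if w < 2:
            raise ValueError("window must contain at least 2 samples")
        return w, s


@dataclass
class FeatureSeries:
    """Windowed features of one EMG channel.

    ``values`` is a [time-step x feature] matrix; ``times`` holds the
    window-end timestamps in seconds, so each row depends only on past
    samples (causal alignment).
    """

    channel: str
    feature_names: tuple[str, ...]
    values: np.ndarray
    times: np.ndarray

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Feature kernels: each maps windows [k, N] -> [k]
# ---------------------------------------------------------------------------

def _iav(w, eps):
    return np.abs(w).sum(axis=-1)


def _mav(w, eps):
    return np.abs(w).mean(axis=-1)


def _mmav_weights1(n: int) -> np.ndarray:
    i = np.arange(1, n + 1)
    wts = np.full(n, 0.5)
    wts[(i >= 0.25 * n) & (i <= 0.75 * n)] = 1.0
    return wts


def _mmav_weights2(n: int) -> np.ndarray:
    # ramp 0->1 over the first quarter, 1 in the middle, 1->0 over the last
    i = np.arange(1, n + 1, dtype=float)
    wts = np.ones(n)
    lo = i < 0.25 * n
    hi = i > 0.75 * n
    wts[lo] = 4.0 * i[lo] / n
    wts[hi] = 4.0 * (n - i[hi]) / n
    return wts


def _mmav1(w, eps):
    return (np.abs(w) * _mmav_weights1(w.shape[-1])).mean(axis=-1)


def _mmav2(w, eps):
    return (np.abs(w) * _mmav_weights2(w.shape[-1])).mean(axis=-1)


def _ssi(w, eps):
    return (w * w).sum(axis=-1)


def _var(w, eps):
    n = w.shape[-1]
    return (w * w).sum(axis=-1) / (n - 1)


def _rms(w, eps):
    return np.sqrt((w * w).mean(axis=-1))


def _wl(w, eps):
    return np.abs(np.diff(w, axis=-1)).sum(axis=-1)


def _log(w, eps):
    a = np.abs(w)
    n_tiny = int((a < LOG_FLOOR).sum())
    if n_tiny:
        warnings.warn(
            f"LOG: {n_tiny} sample(s) below {LOG_FLOOR:g} V clamped before log",
            RuntimeWarning,
            stacklevel=3,
        )
        a = np.maximum(a, LOG_FLOOR)
    return np.exp(np.log(a).mean(axis=-1))


def _zc(w, eps):
    x0, x1 = w[..., :-1], w[..., 1:]
    qualified = (x0 * x1 < 0) & (np.abs(x0 - x1) >= eps)
    return qualified.sum(axis=-1).astype(float)


def _ssc(w, eps):
    d1 = w[..., 1:-1] - w[..., :-2]
    d2 = w[..., 1:-1] - w[..., 2:]
    qualified = (d1 * d2 > 0) & (np.maximum(np.abs(d1), np.abs(d2)) >= eps)
    return qualified.sum(axis=-1).astype(float)


def _wamp(w, eps):
    return (np.abs(np.diff(w, axis=-1)) >= eps).sum(axis=-1).astype(float)


def _aac(w, eps):
    return np.abs(np.diff(w, axis=-1)).sum(axis=-1) / w.shape[-1]


def _dasdv(w, eps):
    d = np.diff(w, axis=-1)
    return np.sqrt((d * d).sum(axis=-1) / (w.shape[-1] - 1))


_KERNELS = {
    "IAV": _iav, "MAV": _mav, "MMAV1": _mmav1, "MMAV2": _mmav2,
    "SSI": _ssi, "VAR": _var, "RMS": _rms, "WL": _wl, "LOG": _log,
    "ZC": _zc, "SSC": _ssc, "WAMP": _wamp, "AAC": _aac, "DASDV": _dasdv,
}
assert tuple(_KERNELS) == FEATURE_NAMES


def compute_feature(window: np.ndarray, name: str, eps: float = 0.0) -> float:
    """Compute one named feature on one window of samples.

    ``eps`` (volts) is the amplitude threshold for the counting features
    ZC, SSC and WAMP; it is ignored by the others.
    """
    if name not in _KERNELS:
        raise KeyError(
            f"unknown feature {name!r}; registered features: {', '.join(FEATURE_NAMES)}"
        )
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("window must be a 1-D vector with at least 2 samples")
    return float(_KERNELS[name](w[None, :], eps)[0])


def estimate_eps(x: np.ndarray, fraction: float = 0.01) -> float:
    """Default counting threshold: a small fraction of the background RMS.

    The background (rest-phase) RMS is estimated robustly from the whole
    channel as ``median(|x|)/0.6745``, the normal-consistent MAD scale,
    which is insensitive to the sparse movement bursts.
    """
    x = np.asarray(x, dtype=float)
    sigma = float(np.median(np.abs(x))) / 0.6745
    return fraction * sigma


def feature_matrix(
    rec: Recording,
    spec: WindowSpec | None = None,
    names: tuple[str, ...] = FEATURE_NAMES,
    eps: float | dict[str, float] | None = None,
) -> dict[str, FeatureSeries]:
    """Compute feature time series for every EMG channel of a session.

    The recording is assumed preprocessed.  Windows are right-aligned:
    the row at time *t* summarizes samples ``(t - length, t]``.  Returns
    ``{channel_name: FeatureSeries}``; channels shorter than one window
    yield an empty series with a warning.
    """
    spec = spec or WindowSpec()
    w_len, step = spec.in_samples(rec.sample_rate)
    for nm in names:
        if nm not in _KERNELS:
            raise KeyError(
                f"unknown feature {nm!r}; registered: {', '.join(FEATURE_NAMES)}"
            )
    out: dict[str, FeatureSeries] = {}
    n = rec.n_samples
    if n < w_len:
        warnings.warn("recording shorter than one window; empty feature series")
        for name in rec.channel_names:
            out[name] = FeatureSeries(
                channel=name,
                feature_names=tuple(names),
                values=np.zeros((0, len(names))),
                times=np.zeros(0),
            )
        return out
    n_steps = (n - w_len) // step + 1
    # window-end timestamps (time of the last sample in each window)
    end_idx = w_len - 1 + step * np.arange(n_steps)
    times = end_idx / rec.sample_rate
    for ci, name in enumerate(rec.channel_names):
        x = rec.emg[:, ci]
        windows = np.lib.stride_tricks.sliding_window_view(x, w_len)[::step]
        if isinstance(eps, dict):
            eps_c = eps.get(name, 0.0)
        elif eps is None:
            eps_c = estimate_eps(x)
        else:
            eps_c = float(eps)
        vals = np.column_stack([_KERNELS[nm](windows, eps_c) for nm in names])
        out[name] = FeatureSeries(
            channel=name, feature_names=tuple(names), values=vals, times=times.copy()
        )
    return out
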