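"""Two-component Gaussian mixture onset model with adaptive threshold.

Each EMG feature's marginal density is modeled as a two-component scalar
Gaussian mixture

    p(x | lambda) = w_r N(x; mu_r, var_r) + w_m N(x; mu_m, var_m)

whose components describe the *rest* and *movement* phases.  Parameters
are fit unsupervised by expectation-maximization; the decision threshold
``theta`` between rest and movement is the feature value at which the
two weighted component densities are equal (the minimum-error boundary).

During testing the model tracks non-stationarity (electrode drift,
changing background noise, fatigue) through a recursive update with
forgetting factor ``alpha = (L - 1) / L``:

    w_i   <- alpha w_i + (1 - alpha) p(i | x)
    mu_i  <- [alpha w_i mu_i + (1 - alpha) p(i | x) x] / w_i'
    var_i <- [alpha w_i var_i + (1 - alpha) p(i | x) (x - mu_i')^2] / w_i'

where ``p(i | x)`` is the posterior responsibility of component *i* for
the new sample and primes denote updated values.  The threshold is
re-derived after every update, so it adapts at the feature update rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AdaptiveState",
    "DegenerateFitError",
    "EmFit",
    "GmmParams",
    "StreamResult",
    "classify_stream",
    "classify_streams",
    "em_fit",
    "optimal_threshold",
    "responsibilities",
    "sequential_update",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def save_models(models: dict, path, metadata: dict | None = None) -> None:
    """Write trained per-(muscle, feature) models as flat key-value text."""
    from pathlib import Path

    lines = [f"# {k}: {v}" for k, v in (metadata or {}).items()]
    for (muscle, feat), p in models.items():
        prefix = f"{muscle}.{feat}"
        for fld in ("w_rest", "w_mov", "mu_rest", "mu_mov", "var_rest", "var_mov"):
            lines.append(f"{prefix}.{fld} = {getattr(p, fld)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_models(path) -> dict:
    """Read a model file written by :func:`save_models`."""
    from pathlib import Path

    raw: dict[tuple[str, str], dict[str, float]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        muscle, feat, fld = key.strip().rsplit(".", 2)
        raw.setdefault((muscle, feat), {})[fld] = float(val)
    return {k: GmmParams(**v) for k, v in raw.items()}


class DegenerateFitError(ValueError):
    """Raised when the training data cannot support a two-component fit."""


@dataclass(frozen=True)
class GmmParams:
    """Parameter set of the two-component mixture.

    Invariants: weights sum to one and lie in (0, 1); variances are
    positive; by convention the rest component is the lower-mean one.
    """

    w_rest: float
    w_mov: float
    mu_rest: float
    mu_mov: float
    var_rest: float
    var_mov: float

    def __post_init__(self) -> None:
        if not (0.0 < self.w_rest < 1.0 and 0.0 < self.w_mov < 1.0):
            raise ValueError("mixture weights must lie in (0, 1)")
        if abs(self.w_rest + self.w_mov - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.var_rest <= 0 or self.var_mov <= 0:
            raise ValueError("variances must be positive")
        if self.mu_rest > self.mu_mov:
            raise ValueError("labeling convention requires mu_rest <= mu_mov")

    @property
    def is_degenerate(self) -> bool:
        """Components with coincident means cannot separate the phases."""
        scale = max(abs(self.mu_rest), abs(self.mu_mov), 1e-300)
        return abs(self.mu_mov - self.mu_rest) <= 1e-12 * scale

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.w_rest, self.w_mov, self.mu_rest, self.mu_mov,
             self.var_rest, self.var_mov]
        )


@dataclass(frozen=True)
class EmFit:
    """EM result: parameters plus convergence diagnostics."""

    params: GmmParams
    converged: bool
    n_iter: int
    log_likelihood: float
    variance_floored: bool = False


@dataclass(frozen=True)
class AdaptiveState:
    """Running state of the sequential (forgetting-factor) estimator."""

    params: GmmParams
    alpha: float
    theta: float
    step_index: int = 0
    degenerate: bool = False

    @classmethod
    def from_memory_length(cls, params: GmmParams, L: int) -> "AdaptiveState":
        """Build a state whose forgetting factor is ``(L - 1) / L``."""
        if L < 1:
            raise ValueError("memory length L must be >= 1")
        alpha = (L - 1) / L if np.isfinite(L) else 1.0
        theta, degen = _threshold_flagged(params)
        return cls(params=params, alpha=alpha, theta=theta,
                   step_index=0, degenerate=degen)


# ---------------------------------------------------------------------------
# Density helpers
# ---------------------------------------------------------------------------

def _log_norm(x: np.ndarray | float, mu: float, var: float) -> np.ndarray | float:
    return -0.5 * (_LOG_2PI + np.log(var)) - (x - mu) ** 2 / (2.0 * var)


def responsibilities(x: float, params: GmmParams) -> tuple[float, float]:
    """Posterior probability of each component for one sample.

    Computed in the log domain so that samples far in either tail do not
    underflow; if both component densities underflow even after
    renormalization, the sample is assigned with probability one to the
    nearer-mean component.
    """
    lr = np.log(params.w_rest) + _log_norm(x, params.mu_rest, params.var_rest)
    lm = np.log(params.w_mov) + _log_norm(x, params.mu_mov, params.var_mov)
    m = max(lr, lm)
    if not np.isfinite(m):
        near_rest = abs(x - params.mu_rest) <= abs(x - params.mu_mov)
        return (1.0, 0.0) if near_rest else (0.0, 1.0)
    er, em = np.exp(lr - m), np.exp(lm - m)
    p_rest = er / (er + em)
    return float(p_rest), float(1.0 - p_rest)


# ---------------------------------------------------------------------------
# EM fit
# ---------------------------------------------------------------------------

def em_fit(
    samples: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    n_train_floor: int = 50,
    var_floor_ratio: float = 1e-12,
    n_restarts: int = 0,
) -> EmFit:
    """Maximum-likelihood fit of the two-component mixture by EM.

    Iterates expectation and maximization steps until the largest
    absolute change over all six parameters falls below ``tol`` (default
    1e-6) or ``max_iter`` is reached.  Components are initialized by a
    median split of the sorted samples; optional random restarts
    (``n_restarts`` > 0, seeded) perturb the initial means and keep the
    best-likelihood solution.  Component variances are floored at
    ``var_floor_ratio`` times the sample variance; a floored fit is
    flagged, an all-identical sample set raises
    :class:`DegenerateFitError`.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < n_train_floor:
        raise ValueError(
            f"training set has {x.size} samples; at least {n_train_floor} required"
        )
    if not np.isfinite(x).all():
        raise ValueError("training samples must be finite")
    s_var = float(np.var(x))
    if s_var <= 0.0:
        raise DegenerateFitError("zero-variance training data")
    var_floor = var_floor_ratio * s_var

    med = float(np.median(x))
    inits = [_split_init(x, med)]
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        span = float(x.max() - x.min())
        for _ in range(n_restarts):
            jitter = rng.normal(scale=0.1 * span, size=2)
            inits.append(_split_init(x, med, jitter))

    best: EmFit | None = None
    for init in inits:
        fit = _em_run(x, init, tol, max_iter, var_floor)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    return best


def _split_init(
    x: np.ndarray, med: float, jitter: tuple[float, float] | np.ndarray = (0.0, 0.0)
) -> np.ndarray:
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # heavily tied data; fall back to quartile split
        q = np.quantile(x, 0.75)
        lo, hi = x[x <= q], x[x > q]
    if hi.size == 0:
        raise DegenerateFitError("training data has no spread above the median")
    mu = np.array([lo.mean() + jitter[0], hi.mean() + jitter[1]])
    overall = max(float(np.var(x)), 1e-300)
    var = np.array([
        max(float(np.var(lo)), 1e-6 * overall),
        max(float(np.var(hi)), 1e-6 * overall),
    ])
    return np.array([0.5, 0.5, mu[0], mu[1], var[0], var[1]])


def _em_run(
    x: np.ndarray, init: np.ndarray, tol: float, max_iter: int, var_floor: float
) -> EmFit:
    w = init[0:2].copy()
    mu = init[2:4].copy()
    var = init[4:6].copy()
    floored = False
    converged = False
    it = 0
    ll = -np.inf
    for it in range(1, max_iter + 1):
        prev = np.concatenate([w, mu, var])
        # E step (log domain)
        lr = np.log(w[0]) + _log_norm(x, mu[0], var[0])
        lm = np.log(w[1]) + _log_norm(x, mu[1], var[1])
        m = np.maximum(lr, lm)
        er, em_ = np.exp(lr - m), np.exp(lm - m)
        denom = er + em_
        g = er / denom  # responsibility of component 0
        ll = float(np.sum(m + np.log(denom)))
        # M step
        n0 = g.sum()
        n1 = x.size - n0
        if n0 <= 0 or n1 <= 0:
            raise DegenerateFitError("a mixture component lost all responsibility")
        w = np.array([n0, n1]) / x.size
        mu = np.array([(g * x).sum() / n0, ((1 - g) * x).sum() / n1])
        var = np.array([
            (g * (x - mu[0]) ** 2).sum() / n0,
            ((1 - g) * (x - mu[1]) ** 2).sum() / n1,
        ])
        if (var < var_floor).any():
            floored = True
            var = np.maximum(var, var_floor)
        if mu[0] > mu[1]:
            w, mu, var = w[::-1], mu[::-1], var[::-1]
        cur = np.concatenate([w, mu, var])
        if np.max(np.abs(cur - prev)) < tol:
            converged = True
            break
    params = GmmParams(
        w_rest=float(w[0]), w_mov=float(w[1]),
        mu_rest=float(mu[0]), mu_mov=float(mu[1]),
        var_rest=float(var[0]), var_mov=float(var[1]),
    )
    return EmFit(params=params, converged=converged, n_iter=it,
                 log_likelihood=ll, variance_floored=floored)


# ---------------------------------------------------------------------------
# Optimal threshold
# ---------------------------------------------------------------------------

def _threshold_flagged(params: GmmParams) -> tuple[float, bool]:
    """Minimum-error threshold and a degenerate-solution flag.

    Solves ``w_r N(theta; mu_r, var_r) = w_m N(theta; mu_m, var_m)``.
    Taking logs turns this into a quadratic in ``theta`` when variances
    differ and a linear equation when they coincide; the root inside
    ``[mu_rest, mu_mov]`` is the decision boundary.  Coincident means
    return the common mean flagged degenerate; if no root falls in the
    inter-mean interval the nearest root is returned, flagged.
    """
    w_r, w_m = params.w_rest, params.w_mov
    mu_r, mu_m = params.mu_rest, params.mu_mov
    v_r, v_m = params.var_rest, params.var_mov
    if params.is_degenerate:
        return 0.5 * (mu_r + mu_m), True
    # log-equality: (t-mu_r)^2/v_r - (t-mu_m)^2/v_m = C
    C = 2.0 * (np.log(w_r) - np.log(w_m)) + np.log(v_m) - np.log(v_r)
    a = 1.0 / v_r - 1.0 / v_m
    b = -2.0 * (mu_r / v_r - mu_m / v_m)
    c = mu_r**2 / v_r - mu_m**2 / v_m - C
    rel = abs(a) * max(v_r, v_m)
    if rel < 1e-12:  # equal variances: linear equation
        theta = 0.5 * (mu_r + mu_m) + v_r * np.log(w_r / w_m) / (mu_m - mu_r)
        inside = mu_r <= theta <= mu_m
        return float(theta), not inside
    disc = b * b - 4.0 * a * c
    if disc < 0.0:  # one weighted density dominates everywhere
        return 0.5 * (mu_r + mu_m), True
    sq = np.sqrt(disc)
    roots = np.array([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    inside = (roots >= mu_r) & (roots <= mu_m)
    if inside.any():
        return float(roots[inside][0]), False
    # no root between the means: take the root nearest the interval
    dist = np.minimum(np.abs(roots - mu_r), np.abs(roots - mu_m))
    return float(roots[np.argmin(dist)]), True


def optimal_threshold(params: GmmParams) -> float:
    """Feature value where the weighted rest/movement densities cross."""
    theta, _ = _threshold_flagged(params)
    return theta


# ---------------------------------------------------------------------------
# Sequential adaptation
# ---------------------------------------------------------------------------

def sequential_update(
    state: AdaptiveState, x_new: float, var_floor: float = 1e-30
) -> AdaptiveState:
    """Fold one new observation into the adaptive model.

    Applies the forgetting-factor recursion to weights, means and
    variances using the responsibilities under the *current* parameters,
    re-sorts components so the rest component keeps the lower mean, and
    re-derives the threshold.  With ``alpha = 1`` the update is a strict
    no-op.  The weight normalization ``w_rest + w_mov = 1`` is preserved
    exactly by construction.
    """
    a = state.alpha
    if a >= 1.0:
        return replace(state, step_index=state.step_index + 1)
    p = state.params
    pr, pm = responsibilities(x_new, p)
    w_r = a * p.w_rest + (1 - a) * pr
    # algebraically w_m = a*w_mov + (1-a)*pm; computing it as the
    # complement keeps the weight normalization exact in floating point
    w_m = 1.0 - w_r
    mu_r = (a * p.w_rest * p.mu_rest + (1 - a) * pr * x_new) / w_r
    mu_m = (a * p.w_mov * p.mu_mov + (1 - a) * pm * x_new) / w_m
    v_r = (a * p.w_rest * p.var_rest + (1 - a) * pr * (x_new - mu_r) ** 2) / w_r
    v_m = (a * p.w_mov * p.var_mov + (1 - a) * pm * (x_new - mu_m) ** 2) / w_m
    floored = v_r < var_floor or v_m < var_floor
    v_r, v_m = max(v_r, var_floor), max(v_m, var_floor)
    if mu_r > mu_m:
        w_r, w_m = w_m, w_r
        mu_r, mu_m = mu_m, mu_r
        v_r, v_m = v_m, v_r
    new_params = GmmParams(w_rest=w_r, w_mov=w_m, mu_rest=mu_r, mu_mov=mu_m,
                           var_rest=v_r, var_mov=v_m)
    theta, degen = _threshold_flagged(new_params)
    return AdaptiveState(params=new_params, alpha=a, theta=theta,
                         step_index=state.step_index + 1,
                         degenerate=degen or floored)


# ---------------------------------------------------------------------------
# Stream classification
# ---------------------------------------------------------------------------

@dataclass
class StreamResult:
    """Per-step labels (0 = rest, 1 = movement) and threshold trace."""

    labels: np.ndarray
    theta_trace: np.ndarray
    final_states: list[AdaptiveState]


def classify_stream(
    series: np.ndarray, init: GmmParams, L: int = 1000
) -> StreamResult:
    """Classify one feature stream with the adaptive threshold.

    At every step the sample is compared against the current threshold
    (``x >= theta`` is movement, matching the convention that values
    strictly below the threshold are rest) and the model is then updated
    with that sample.  Deterministic given inputs.
    """
    res = classify_streams(np.asarray(series, float)[:, None], [init], L)
    return res


def classify_streams(
    X: np.ndarray, inits: list[GmmParams] | tuple[GmmParams, ...], L: int = 1000
) -> StreamResult:
    """Vectorized :func:`classify_stream` over parallel feature streams.

    ``X`` is [time-step x stream]; ``inits`` holds one parameter set per
    stream.  Streams are independent; batching them amortizes the
    per-step cost.  Semantics per stream are identical to the scalar
    sequential update (same recursion, same threshold solve, same
    underflow handling).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be [time-step, stream]")
    T, K = X.shape
    if len(inits) != K:
        raise ValueError("one initial parameter set per stream required")
    if L < 1:
        raise ValueError("memory length L must be >= 1")
    a = (L - 1) / L if np.isfinite(L) else 1.0  # L = inf freezes the model
    one_m_a = 1.0 - a

    arr = np.array([p.as_array() for p in inits], dtype=float).T
    w_r, w_m, mu_r, mu_m, v_r, v_m = (arr[i].copy() for i in range(6))
    theta = _threshold_vec(w_r, w_m, mu_r, mu_m, v_r, v_m)

    labels = np.zeros((T, K), dtype=np.uint8)
    theta_trace = np.zeros((T, K), dtype=float)
    var_floor = 1e-30

    for t in range(T):
        x = X[t]
        labels[t] = x >= theta
        if one_m_a > 0.0:
            # responsibilities under current params, log domain
            lr = np.log(w_r) - 0.5 * np.log(v_r) - (x - mu_r) ** 2 / (2.0 * v_r)
            lm = np.log(w_m) - 0.5 * np.log(v_m) - (x - mu_m) ** 2 / (2.0 * v_m)
            m = np.maximum(lr, lm)
            er = np.exp(lr - m)
            em_ = np.exp(lm - m)
            pr = er / (er + em_)
            pm = 1.0 - pr
            nw_r = a * w_r + one_m_a * pr
            nw_m = 1.0 - nw_r  # exact complement (see sequential_update)
            nmu_r = (a * w_r * mu_r + one_m_a * pr * x) / nw_r
            nmu_m = (a * w_m * mu_m + one_m_a * pm * x) / nw_m
            nv_r = (a * w_r * v_r + one_m_a * pr * (x - nmu_r) ** 2) / nw_r
            nv_m = (a * w_m * v_m + one_m_a * pm * (x - nmu_m) ** 2) / nw_m
            np.maximum(nv_r, var_floor, out=nv_r)
            np.maximum(nv_m, var_floor, out=nv_m)
            swap = nmu_r > nmu_m
            if swap.any():
                w_r = np.where(swap, nw_m, nw_r)
                w_m = np.where(swap, nw_r, nw_m)
                mu_r = np.where(swap, nmu_m, nmu_r)
                mu_m = np.where(swap, nmu_r, nmu_m)
                v_r = np.where(swap, nv_m, nv_r)
                v_m = np.where(swap, nv_r, nv_m)
            else:
                w_r, w_m, mu_r, mu_m, v_r, v_m = nw_r, nw_m, nmu_r, nmu_m, nv_r, nv_m
            theta = _threshold_vec(w_r, w_m, mu_r, mu_m, v_r, v_m)
        theta_trace[t] = theta

    finals = []
    for k in range(K):
        p = GmmParams(w_rest=float(w_r[k]), w_mov=float(w_m[k]),
                      mu_rest=float(mu_r[k]), mu_mov=float(mu_m[k]),
                      var_rest=float(v_r[k]), var_mov=float(v_m[k]))
        th, degen = _threshold_flagged(p)
        finals.append(AdaptiveState(params=p, alpha=a, theta=th,
                                    step_index=T, degenerate=degen))
    if K == 1:
        labels = labels[:, 0]
        theta_trace = theta_trace[:, 0]
    return StreamResult(labels=labels, theta_trace=theta_trace, final_states=finals)


def _threshold_vec(w_r, w_m, mu_r, mu_m, v_r, v_m) -> np.ndarray:
    """Vectorized minimum-error threshold (same cases as the scalar solve)."""
    mid = 0.5 * (mu_r + mu_m)
    sep = mu_m - mu_r
    degen = sep <= 1e-12 * np.maximum(np.maximum(np.abs(mu_r), np.abs(mu_m)), 1e-300)
    sep_safe = np.where(degen, 1.0, sep)

    C = 2.0 * (np.log(w_r) - np.log(w_m)) + np.log(v_m) - np.log(v_r)
    a = 1.0 / v_r - 1.0 / v_m
    b = -2.0 * (mu_r / v_r - mu_m / v_m)
    c = mu_r**2 / v_r - mu_m**2 / v_m - C

    equal_var = np.abs(a) * np.maximum(v_r, v_m) < 1e-12
    theta_lin = mid + v_r * np.log(w_r / w_m) / sep_safe

    a_safe = np.where(equal_var, 1.0, a)
    disc = b * b - 4.0 * a_safe * c
    neg_disc = disc < 0.0
    sq = np.sqrt(np.where(neg_disc, 0.0, disc))
    r1 = (-b - sq) / (2.0 * a_safe)
    r2 = (-b + sq) / (2.0 * a_safe)
    in1 = (r1 >= mu_r) & (r1 <= mu_m)
    in2 = (r2 >= mu_r) & (r2 <= mu_m)
    d1 = np.minimum(np.abs(r1 - mu_r), np.abs(r1 - mu_m))
    d2 = np.minimum(np.abs(r2 - mu_r), np.abs(r2 - mu_m))
    theta_quad = np.where(in1, r1, np.where(in2, r2, np.where(d1 <= d2, r1, r2)))
    theta_quad = np.where(neg_disc, mid, theta_quad)

    theta = np.where(equal_var, theta_lin, theta_quad)
    return np.where(degen, mid, theta)
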