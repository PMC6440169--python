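"""Information-theoretic feature and muscle selection.

The subject-independent feature set is chosen by measuring, in bits, how
much each candidate feature tells about the rest/movement phase, and
decomposing the joint information of feature groups into

    I(R; F) = I_lin + I_sig_sim + I_cor_ind + I_cor_dep

where ``I_lin`` sums the single-feature informations, the non-positive
signal-similarity term ``I_sig_sim`` quantifies redundancy between
features, and the two correlation terms quantify synergy (extra
information available only from the joint response).  The decomposition
is computed constructively on binned (discretized) responses:

* ``I_lin = sum_c I(R; F_c)``;
* the conditionally-independent surrogate has
  ``P_ind(f | r) = prod_c P(f_c | r)`` and information ``I_ind``, giving
  ``I_sig_sim = I_ind - I_lin``;
* ``I_cor_dep`` is the stimulus-dependent correlational divergence
  ``sum_r P(r) sum_f P(f|r) log2[P(f|r) P_ind(f) / (P_ind(f|r) P(f))]``;
* ``I_cor_ind = I(R; F) - I_ind - I_cor_dep``, so the four terms sum to
  the joint information exactly.

Selection proceeds in three steps: screen features against a white-noise
baseline (Kruskal-Wallis with post-hoc comparisons), drop features whose
pairwise correlation terms are negative (non-synergistic) keeping the
most informative member of each redundant group, and finally rank
muscles by the joint information of the surviving feature set to pick
the panel for the info-based multi-muscle detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BinnedResponse",
    "InfoBreakdown",
    "WindowComparison",
    "bin_feature",
    "compare_window_lengths",
    "info_breakdown",
    "mutual_info",
    "rank_muscles",
    "screen_features",
    "select_feature_set",
]

#: Default number of amplitude bins per channel and joint-state cap.
DEFAULT_N_BINS = 4
JOINT_STATE_CAP = 256


@dataclass
class BinnedResponse:
    """Phase labels with per-channel discretized feature responses.

    ``labels`` holds the phase (0 = rest, 1 = movement) per time step;
    ``bins`` is [step x channel] of integer bin indices; ``edges`` the
    interior quantile edges used per channel.
    """

    labels: np.ndarray
    bins: np.ndarray
    n_bins: int
    edges: list[np.ndarray]
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.bins = np.asarray(self.bins)
        if self.bins.ndim == 1:
            self.bins = self.bins[:, None]
        if self.labels.shape[0] != self.bins.shape[0]:
            raise ValueError("labels and bins must share length")
        if self.bins.size and self.bins.max() >= self.n_bins:
            raise ValueError("bin index out of range")

    @property
    def n_channels(self) -> int:
        return self.bins.shape[1]


@dataclass(frozen=True)
class InfoBreakdown:
    """Joint information (bits) and its four additive components."""

    I_total: float
    I_lin: float
    I_sig_sim: float
    I_cor_ind: float
    I_cor_dep: float

    @property
    def synergy(self) -> float:
        """Total correlational (synergy) contribution."""
        return self.I_cor_ind + self.I_cor_dep

    @property
    def redundancy(self) -> float:
        """Non-positive signal-similarity (redundancy) contribution."""
        return self.I_sig_sim


def bin_feature(values: np.ndarray, n_bins: int = DEFAULT_N_BINS):
    """Equipopulated (quantile) binning of one feature series.

    Returns ``(bin_indices, interior_edges)``.  Binning is rank-based,
    so any monotone transform of the values leaves the assignment
    unchanged.  Raises if the values cannot support ``n_bins`` distinct
    quantile edges (e.g. constant input).
    """
    values = np.asarray(values, dtype=float).ravel()
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.unique(values).size < n_bins:
        raise ValueError(
            f"only {np.unique(values).size} distinct values; "
            f"use fewer than {n_bins} bins"
        )
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = np.quantile(values, qs)
    if np.unique(edges).size < edges.size:
        raise ValueError(
            "quantile edges are tied (heavily repeated values); use fewer bins"
        )
    idx = np.searchsorted(edges, values, side="right")
    return idx.astype(np.int64), edges


def _joint_states(bins: np.ndarray, n_bins: int, channels) -> np.ndarray:
    """Collapse selected channels into a single joint-state index."""
    sub = bins[:, list(channels)]
    n_states = n_bins ** sub.shape[1]
    if n_states > JOINT_STATE_CAP:
        raise ValueError(
            f"joint state space {n_states} exceeds cap {JOINT_STATE_CAP}; "
            "use fewer channels or bins"
        )
    state = np.zeros(sub.shape[0], dtype=np.int64)
    for c in range(sub.shape[1]):
        state = state * n_bins + sub[:, c]
    return state


def _plugin_mi_from_counts(counts: np.ndarray) -> float:
    """Plug-in mutual information (bits) from an [R x F] count table."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    pr = p.sum(axis=1, keepdims=True)
    pf = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pr * pf))
    return float(np.nansum(terms))


def _pt_bias(counts: np.ndarray) -> float:
    """Panzeri-Treves first-order bias of the plug-in estimate (bits).

    ``bias = [sum_r (R_r - 1) - (R - 1)] / (2 N ln 2)`` with ``R_r`` the
    number of occupied response bins given phase ``r`` and ``R`` the
    number of occupied bins overall (naive occupancy counting).
    """
    n = counts.sum()
    if n == 0:
        return 0.0
    r_occ = (counts.sum(axis=0) > 0).sum()
    r_per = (counts > 0).sum(axis=1)
    return (float((r_per - 1).sum()) - float(r_occ - 1)) / (2.0 * n * np.log(2))


def mutual_info(
    binned: BinnedResponse,
    channels=None,
    bias_correction: str | bool = "auto",
) -> float:
    """Information (bits) the selected channels carry about the phase.

    Plug-in estimate on the joint binned states, optionally reduced by
    the Panzeri-Treves first-order bias term.  ``bias_correction`` may
    be True, False or ``"auto"`` (on when fewer than 10,000 samples).
    """
    if channels is None:
        channels = range(binned.n_channels)
    channels = list(channels)
    if not channels:
        raise ValueError("channel subset must be non-empty")
    state = _joint_states(binned.bins, binned.n_bins, channels)
    counts = _count_table(binned.labels, state)
    mi = _plugin_mi_from_counts(counts)
    n = binned.labels.size
    if bias_correction == "auto":
        bias_correction = n < 10_000
    if bias_correction:
        mi -= _pt_bias(counts)
    return mi


def _count_table(labels: np.ndarray, states: np.ndarray) -> np.ndarray:
    r_vals = np.unique(labels)
    n_states = int(states.max()) + 1 if states.size else 1
    table = np.zeros((r_vals.size, n_states))
    for i, r in enumerate(r_vals):
        table[i] = np.bincount(states[labels == r], minlength=n_states)
    return table


def info_breakdown(binned: BinnedResponse, channels=None) -> InfoBreakdown:
    """Four-term decomposition of the joint information about the phase.

    Computed plug-in (no bias correction) so the sum identity
    ``I_total = I_lin + I_sig_sim + I_cor_ind + I_cor_dep`` holds
    exactly.  A single channel returns ``(I, I, 0, 0, 0)``.
    """
    if channels is None:
        channels = range(binned.n_channels)
    channels = list(channels)
    if not channels:
        raise ValueError("channel subset must be non-empty")
    labels = binned.labels
    n = labels.size
    r_vals = np.unique(labels)
    p_r = np.array([(labels == r).mean() for r in r_vals])

    # single-channel (linear) informations
    singles = []
    for c in channels:
        counts = _count_table(labels, binned.bins[:, c].astype(np.int64))
        singles.append(_plugin_mi_from_counts(counts))
    I_lin = float(sum(singles))

    if len(channels) == 1:
        return InfoBreakdown(I_total=singles[0], I_lin=singles[0],
                             I_sig_sim=0.0, I_cor_ind=0.0, I_cor_dep=0.0)

    state = _joint_states(binned.bins, binned.n_bins, channels)
    n_states = binned.n_bins ** len(channels)
    counts = np.zeros((r_vals.size, n_states))
    for i, r in enumerate(r_vals):
        counts[i] = np.bincount(state[labels == r], minlength=n_states)
    p_f_given_r = counts / counts.sum(axis=1, keepdims=True)
    p_f = (p_r[:, None] * p_f_given_r).sum(axis=0)
    I_total = _plugin_mi_from_counts(counts)

    # conditionally-independent surrogate: product of per-channel
    # phase-conditional marginals, expanded over the joint state space
    p_ind_given_r = np.ones((r_vals.size, n_states))
    states_idx = np.arange(n_states)
    digits = []
    for _ in channels:
        digits.append(states_idx % binned.n_bins)
        states_idx = states_idx // binned.n_bins
    digits = digits[::-1]  # first channel is the most significant digit
    for ci, c in enumerate(channels):
        marg = _count_table(labels, binned.bins[:, c].astype(np.int64))
        marg = marg / marg.sum(axis=1, keepdims=True)
        if marg.shape[1] < binned.n_bins:
            marg = np.pad(marg, ((0, 0), (0, binned.n_bins - marg.shape[1])))
        p_ind_given_r *= marg[:, digits[ci]]
    p_ind = (p_r[:, None] * p_ind_given_r).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        terms_ind = p_r[:, None] * p_ind_given_r * np.log2(
            p_ind_given_r / p_ind[None, :]
        )
    I_ind = float(np.nansum(terms_ind))
    I_sig_sim = I_ind - I_lin

    # stimulus-dependent correlation term: divergence between the true
    # phase-conditional joint and its independent surrogate, weighted by
    # how that changes the decodable information
    with np.errstate(divide="ignore", invalid="ignore"):
        log_arg = (p_f_given_r * p_ind[None, :]) / (p_ind_given_r * p_f[None, :])
        terms_dep = p_r[:, None] * p_f_given_r * np.log2(log_arg)
    I_cor_dep = float(np.nansum(terms_dep))
    I_cor_ind = I_total - I_ind - I_cor_dep
    return InfoBreakdown(I_total=I_total, I_lin=I_lin, I_sig_sim=I_sig_sim,
                         I_cor_ind=I_cor_ind, I_cor_dep=I_cor_dep)


# ---------------------------------------------------------------------------
# Screening and selection
# ---------------------------------------------------------------------------

def screen_features(
    info_by_feature: dict[str, np.ndarray],
    noise_info: np.ndarray,
    alpha: float = 0.001,
) -> list[str]:
    """Retain features carrying significantly more phase information
    than white noise.

    ``info_by_feature`` maps each feature to its information values
    across units (e.g. subject x muscle replicates); ``noise_info`` is
    the same quantity computed by the identical pipeline on white
    Gaussian noise.  A Kruskal-Wallis test across all groups gates
    per-feature post-hoc comparisons against the noise baseline
    (one-sided Mann-Whitney at level ``alpha``).
    """
    if len(info_by_feature) < 2:
        raise ValueError("need at least 2 features to screen")
    noise_info = np.asarray(noise_info, dtype=float)
    groups = {k: np.asarray(v, dtype=float) for k, v in info_by_feature.items()}
    for name, v in groups.items():
        if v.size < 3:
            raise ValueError(f"feature {name!r} has fewer than 3 replicates")
    if noise_info.size < 3:
        raise ValueError("noise baseline has fewer than 3 replicates")
    _, kw_p = stats.kruskal(*groups.values(), noise_info)
    if kw_p >= alpha:
        return []
    retained = []
    for name in sorted(groups):
        _, p = stats.mannwhitneyu(groups[name], noise_info, alternative="greater")
        if p < alpha:
            retained.append(name)
    return retained


def select_feature_set(
    retained: list[str],
    pairwise: dict[tuple[str, str], InfoBreakdown],
    mean_info: dict[str, float],
    synergy_tol: float = 0.0,
) -> list[str]:
    """Minimal-redundancy, maximal-synergy feature subset.

    Builds a graph on the retained features with an edge wherever the
    pairwise correlation (synergy) term is negative — the two features
    are non-synergistic, i.e. jointly worth less than their parts — and
    keeps, within each connected component, the single feature with the
    highest mean single-feature information.  Features with no negative
    edge survive untouched.  Returns the kept features sorted by the
    original retained order.
    """
    if not retained:
        raise ValueError("retained feature list is empty")
    order = {f: i for i, f in enumerate(retained)}
    parent = {f: f for f in retained}

    def find(f):
        while parent[f] != f:
            parent[f] = parent[parent[f]]
            f = parent[f]
        return f

    for (f1, f2), bd in pairwise.items():
        if f1 in order and f2 in order and bd.synergy < -abs(synergy_tol):
            r1, r2 = find(f1), find(f2)
            if r1 != r2:
                parent[r1] = r2
    components: dict[str, list[str]] = {}
    for f in retained:
        components.setdefault(find(f), []).append(f)
    kept = [max(members, key=lambda f: (mean_info[f], -order[f]))
            for members in components.values()]
    return sorted(kept, key=lambda f: order[f])


def rank_muscles(
    info_by_muscle: dict[str, float], top_p: int = 3
) -> tuple[list[str], list[str]]:
    """Order muscles by information content; return (ranking, top-P panel).

    ``info_by_muscle`` maps each muscle to the joint information (bits)
    its selected feature set carries about the phase.  Ties break
    alphabetically for determinism.
    """
    ranking = sorted(info_by_muscle, key=lambda m: (-info_by_muscle[m], m))
    return ranking, ranking[:top_p]


@dataclass(frozen=True)
class WindowComparison:
    """Friedman + pairwise Wilcoxon report across window lengths."""

    lengths_ms: tuple[float, ...]
    friedman_stat: float
    friedman_p: float
    wilcoxon_p: dict[tuple[float, float], float]


def compare_window_lengths(info_tables: dict[float, np.ndarray]) -> WindowComparison:
    """Test whether feature information depends on the window length.

    ``info_tables`` maps window length (ms) to paired per-unit
    information values (same units, same order).  A Friedman test asks
    whether any length differs; pairwise two-sided Wilcoxon signed-rank
    tests localize the differences.
    """
    lengths = tuple(sorted(info_tables))
    if len(lengths) < 3:
        raise ValueError("need at least 3 window lengths")
    arrays = [np.asarray(info_tables[w], dtype=float) for w in lengths]
    sizes = {a.size for a in arrays}
    if len(sizes) != 1:
        raise ValueError("info tables must be paired (equal lengths)")
    identical = all(np.allclose(a, arrays[0]) for a in arrays[1:])
    if identical:
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.friedmanchisquare(*arrays)
    wil = {}
    for i in range(len(lengths)):
        for j in range(i + 1, len(lengths)):
            a, b = arrays[i], arrays[j]
            if np.allclose(a, b):
                wil[(lengths[i], lengths[j])] = 1.0
            else:
                _, wp = stats.wilcoxon(a, b)
                wil[(lengths[i], lengths[j])] = float(wp)
    return WindowComparison(lengths_ms=lengths, friedman_stat=float(stat),
                            friedman_p=float(p), wilcoxon_p=wil)
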