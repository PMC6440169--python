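# Methods

This note records the model, the estimators, the defaults and the
design choices behind `emgonset`, including what the synthetic data do
and do not establish.

## Signal model and preprocessing

Input sessions are 1 kHz multichannel recordings: seven surface-EMG
channels (Trapezius, Anterior/Posterior Deltoid, Biceps, Triceps,
Flexor/Extensor Carpi Ulnaris), four exoskeleton joint angles (sAA,
sFE, sIE, eFE), the elbow interaction torque, an LED cue code and a
control-mode code. Offline preprocessing applies a 4th-order
Butterworth high-pass at 10 Hz and an IIR notch at 50 Hz (quality
factor Q = 30). Filtering is zero-phase by default so that group delay
cannot bias latency estimates; a `causal=True` mode applies both
filters forward-only for online emulation. The notch's forward-backward
padding is set to one ring length (Q/f₀ seconds) — with the default
6-sample padding its edge transients leak ~8 % of a 50 Hz tone. No
additional low-pass is applied offline; the hardware anti-aliasing
chain is assumed to have band-limited the signal.

## Time-domain features

Fourteen features are computed per 300 ms window, updated every 10 ms,
right-aligned (the timestamp is the window end, so every value is
causal). Nine are amplitude sums/means (IAV, MAV, MMAV1, MMAV2, SSI,
VAR, RMS, WL, LOG) and five are counting/difference statistics (ZC,
SSC, WAMP, AAC, DASDV). Formulas follow the standard
myoelectric-feature literature; for MMAV2 the end-weight ramp is
implemented as `4(N−i)/N` on the last quarter (the form `4(i−N)/N`
printed in parts of the survey literature is negative there and is
evidently a sign typo). The counting features take an amplitude
threshold `eps`, defaulting to 1 % of the channel's background RMS
estimated robustly as `median(|x|)/0.6745` — insensitive to the sparse
movement bursts, so it approximates the rest-phase RMS without needing
labels. LOG clamps |x| at 1e−12 V before the logarithm and warns.

## Two-component mixture and threshold

Each feature's marginal density is a two-component scalar Gaussian
mixture; the lower-mean component is *rest* by convention. EM is
initialized by a median split (weights 0.5/0.5) and iterates until the
largest absolute change across all six parameters falls below 1e−6
(default) or 500 iterations. Optional seeded random restarts perturb
the initial means; they are off by default because the median split is
already reliable for well-separated rest/movement amplitudes. Component
variances are floored at 1e−12 × sample variance and flagged when
floored; zero-variance training data raise a degenerate-fit error.

The decision threshold θ equates the weighted component densities. In
log form this is quadratic in θ for unequal variances (solved in closed
form, taking the root inside [μ_r, μ_m]) and linear for equal
variances. Degenerate cases are flagged: coincident means return the
common mean; when no root lies between the means (one weighted density
dominates) the nearest root is returned. Samples with `x ≥ θ` are
classified movement — rest is strictly `x < θ`, so the boundary itself
goes to movement, the safety-relevant class for triggering assistance.

## Sequential adaptation

During testing the model updates at every 10 ms feature step with
forgetting factor `α = (L−1)/L`:

    w_i ← α w_i + (1−α) p(i|x)
    μ_i ← [α w_i μ_i + (1−α) p(i|x) x] / w_i'
    σ²_i ← [α w_i σ²_i + (1−α) p(i|x) (x − μ_i')²] / w_i'

with responsibilities computed under the pre-update parameters in the
log domain (tail samples that underflow both densities are assigned to
the nearer-mean component). `w_mov` is computed as `1 − w_rest`, which
is algebraically identical (responsibilities sum to one) and keeps the
normalization exact in floating point. Components are re-sorted if
their means cross, and θ is re-derived after every update. The default
memory length is L = 1000 steps (10 s at the 100 Hz update rate):
long enough that a single 1–2 s movement burst cannot drag the rest
component upward, short enough to track within-session drift; it is
exposed in the configuration, and `L = inf` freezes the model (used as
the non-adaptive ablation baseline). Updates begin at the first test
sample with no burn-in. Per-feature models are independent scalar
mixtures; no cross-feature covariance is modeled.

## Detectors

A Type 1 detector majority-votes the M = 4 per-feature decisions of
one muscle: rest requires at least ⌊M/2⌋+1 rest votes, ties go to
movement. A Type 2 detector applies the same rule across the Type 1
outputs of S = 7 muscles, unweighted; the info-based variant restricts
to the P = 3 most informative muscles for the event — the smallest
panel with a strict majority. Onsets are rest→movement transitions
surviving a debounce of `debounce` consecutive movement steps
(default 1, i.e. raw per-step decisions; real deployments will want
more).

## Information-theoretic selection

Feature values are discretized by equipopulated (quantile) binning,
default 4 bins per channel, with a 256-joint-state cap (4 features × 4
bins). Mutual information uses the plug-in estimator on the binned
contingency table; the Panzeri–Treves first-order bias term (with naive
occupancy counts) is subtracted by default when n < 10,000. The
four-term breakdown is computed constructively and plug-in (no bias
correction) so the sum identity holds to machine precision:
`I_lin` sums single-channel informations; the conditionally-independent
surrogate `P_ind(f|r) = Π_c P(f_c|r)` gives `I_ind` and
`I_sig_sim = I_ind − I_lin` (provably ≤ 0); the stimulus-dependent
correlation term is the divergence
`Σ_r P(r) Σ_f P(f|r) log₂[P(f|r)P_ind(f) / (P_ind(f|r)P(f))]`; and
`I_cor_ind` is obtained by subtraction. Term-by-term agreement with the
original binned-response toolbox implementation cannot be verified from
the published text; the implementation is validated instead on limiting
cases (conditional independence ⇒ correlation terms ≈ 0; duplicated
channels ⇒ no information gain and strictly negative similarity term).

Screening compares each feature's per-unit information against a
white-noise baseline produced by the identical pipeline: a
Kruskal–Wallis test across all groups gates per-feature one-sided
Mann–Whitney comparisons at p < 0.001. (A rank-based post hoc is used
rather than a parametric Tukey HSD to stay within the nonparametric
frame of the omnibus test.) Final selection builds a graph on retained
features with edges where the pairwise correlation term is negative
(non-synergistic) and keeps the most informative member of each
connected component. Muscles are ranked by the joint information of
the selected feature set; window lengths (100/300/500 ms) are compared
with a Friedman test plus pairwise Wilcoxon signed-rank tests.

## Reference onsets and scoring

Go-forward reference onset: per joint, the excursion from the
rest-interval baseline must clear a 1° noise floor; the onset candidate
is the first time the excursion reaches 10 % of its own trial peak, and
the earliest candidate across the four joints wins (the aggregation
rule across joints is a package decision — the earliest crossing is the
most conservative choice for latency). Go-backward: the first torque
sample ≥ 2 N·m after LED-off. A trial is a true positive when a
detected onset falls within [t₀ − 0.5 s, t₀ + 1.0 s]; the window is a
package default (observed latencies sit near −0.3…0 s, well inside) and
is configurable. Latency is the first qualifying detection minus t₀;
both mean and median/IQR are reported. Specificity is counted per
feature step over rest-phase steps only; steps in the reaction gap
between cue and EMG onset are phase-ambiguous and excluded by default.
Cross-validation rotates the training session within a subject
(train on one, test on the remaining sessions, average over rotations);
a leave-one-subject-out mode (`subject_holdout_validation`) trains on
pooled sessions of the other subjects instead.

## Synthetic sessions

The generator emulates the reaching protocol: 12 s trials (LED on 6 s —
2.5 s transparent mode then 3.5 s position control — off 6 s), 24
trials per session, 7 sessions per subject, plus one 6 s lead-in rest.
EMG is amplitude-modulated white Gaussian noise,
`σ_c(t) = σ_rest · d(t) · (1 + (g_c − 1)·env(t))`, with a 20 µV
background, raised-cosine burst envelopes rising at the true EMG onset,
per-muscle/per-event gains (reach: Anterior Deltoid 4.0, Posterior
Deltoid 3.0, Biceps 2.5, mild stabilizer activity elsewhere; return:
Extensor Carpi Ulnaris 3.5, Biceps 2.5, Triceps 1.6), an optional
linear background drift d(t) and optional 50 Hz interference. Reaction
times are truncated-normal (0.30 ± 0.05 s, floor 0.1 s); overt motion
follows the EMG onset by an 80 ms electromechanical delay; joint angles
are minimum-jerk profiles (1.2 s); the return torque ramps at 10 N·m/s
and crosses the 2 N·m threshold at a recorded time. Every trial's EMG
onset, kinematic onset and torque crossing, and per-step phase labels,
are exact ground truth.

What the surrogate does *not* reproduce: motor-unit structure and
spectral changes with fatigue, amplitude non-stationarity within a
phase, movement-direction-specific muscle patterns, and cross-channel
correlation of the noise. Consequently amplitude features are far more
discriminable per window here than in real EMG (a 300 ms window of
constant-σ noise estimates σ very precisely), so the near-ceiling
sensitivities and specificities on synthetic benchmarks demonstrate
correctness of the machinery — model fitting, adaptation, voting,
scoring — not expected clinical performance. For the same reason all
amplitude features are mutually redundant here, and the ranking of
strongly-activated muscles can saturate; the muscle-ranking check asks
for recovery of the generated active set, not a full ordering.

## Problem sizes and numerical conventions

The end-to-end benchmark uses the protocol-scale subject (7 sessions ×
24 trials, 1 kHz, ~294 s per session); stream classification batches
all test sessions of a rotation through one vectorized pass, which is
semantically identical to the per-stream recursion. Unit tests run on
2-session, 6-trial subjects. Intervals are half-open `[start, end)` in
0-based samples; time is column-driven; window timestamps are window
ends. Mixture weights live in (0, 1), variances are floored rather than
allowed to collapse, and all randomness flows from explicit seeds
(`SynthConfig.seed`, per-module seeds fanned out from the single global
seed in the CLI configuration).
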