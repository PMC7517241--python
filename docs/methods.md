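# Methods

## Problem setting

Cue-paced motor imagery (MI) elicits event-related desynchronization
(ERD) of the mu rhythm (8–13 Hz) over the sensorimotor cortex
contralateral to the imagined hand: the band-limited power drops during
the imagery interval and recovers afterwards. The classical ERD/S
estimate normalizes trial-averaged instantaneous power to a pre-stimulus
reference interval,

    ζ^P(t) = (ξ(t) − ξ̄) / ξ̄,

with ξ(t) the squared amplitude averaged across trials and ξ̄ its mean
over the reference window. The ratio needs a stable reference level and
many trials. The entropy alternative implemented here tracks the
regularity of the signal in sliding windows instead: it is defined per
single trial and needs no reference power.

## Estimators

All three estimators operate on the delay-vector ("symbol") matrix of a
window: a window of `N` samples yields `Q = N − M` contiguous vectors of
length `M`. The `N − M` convention (rather than the more common
`N − M + 1`) drops one trailing vector; for the window lengths used here
(≥ 250 samples) the difference is negligible, and it is applied
identically at dimensions `M` and `M + 1` so the pattern-count ratio is
internally consistent.

- **Sample entropy**: fraction of ordered vector pairs (self-pairs
  excluded) with Chebyshev distance strictly below the tolerance,
  computed at `M` and `M + 1`; the estimate is `−ln` of the ratio. If no
  pair matches at `M + 1` the estimate is undefined; we return NaN,
  time-courses exclude such windows from the trial average, and feature
  extraction imputes them with the per-feature median.
- **Fuzzy entropy**: the hard count is replaced by the Gaussian
  membership `exp(−(d/ρ_abs)²)` of the Chebyshev distance, so the
  estimate is always finite. We use the standard Gaussian membership —
  negative exponent, tolerance entering squared — because a membership
  must decay with distance and the estimator must be invariant under
  amplitude rescaling; a linear-tolerance denominator would break that
  invariance. The original fuzzy-entropy baseline-removal step
  (subtracting each vector's mean) is deliberately not applied; the
  estimator compares raw delay vectors, like the sample-entropy
  implementation it is paired with.
- **VQEnt**: the delay vectors are compressed by one greedy online pass —
  the first vector seeds the codebook, and vector `q` is admitted iff its
  Euclidean distance to every current code exceeds the tolerance. By
  construction codes are pairwise separated by more than the tolerance
  and every input lies within the tolerance of some code. A one-pass
  probabilistic model is then fitted: (i) Gaussian-similarity membership
  `exp(−‖x̃_q − x̄_q′‖² / 2ρ_abs²)` normalized per input vector; (ii)
  membership-weighted mean `μ_q′` and scalar (isotropic) variance
  `σ²_q′` per code; (iii) likelihood of the window under each code as the
  mean Gaussian similarity of the inputs to `(μ_q′, σ²_q′)`; (iv) prior
  as mean membership; (v) posterior by Bayes' rule. VQEnt is the Shannon
  entropy (nats) of the posterior, bounded by `ln Q′`.

Design choices inside VQEnt that were genuinely open:

- The membership and moment definitions are mutually referential in the
  abstract formulation; we fix the one-pass order membership → moments →
  likelihood/prior → posterior, with no iteration, matching the greedy
  single-pass spirit of the codebook construction.
- The Gaussian similarity bandwidth is the tolerance `ρ_abs` — the only
  scale parameter of the construction; the same `ρ` drives codebook
  admission and the similarity.
- Admission compares the Euclidean distance against `ρ_abs` (i.e.
  `‖·‖² > ρ_abs²`). An alternative reading compares the squared norm
  against `ρ_abs` directly; it is available as
  `build_codebook(..., squared_tolerance=True)` but is not the default
  because it is dimensionally inconsistent and destroys invariance under
  amplitude rescaling.
- Degenerate per-code variances (all soft mass on one point) are floored
  at `1e-12·ρ_abs²`; an all-zero posterior (total likelihood underflow)
  falls back to the prior.

## Tolerance semantics

The tolerance is `ρ` times the standard deviation of the **measured
signal**. For a bare window that is the window's own deviation, which
makes single-window estimates affine-invariant. For sliding-window
time-courses the tolerance is fixed per trial and channel from the whole
trial (`tolerance_scope="trial"`, the default): this is the deviation of
the measured data, and it is essential for the physiology — if each
window is rescaled by its own deviation, the amplitude drop that defines
the ERD is normalized away and the contralateral entropy dip disappears
(we verified numerically that per-window scaling reverses its sign on
synthetic data). Per-window scaling remains available as
`tolerance_scope="window"` for stationarity analyses, e.g. the
white-noise calibration.

Defaults `M = 2`, `ρ = 0.3`, `τ = 1 s`, 90 % window overlap. `τ = 1 s`
at 250 Hz gives `Q = 248` vectors per window, enough for stable pattern
counts; larger windows smooth the trajectory and blur ERD latency.
`ρ ≈ 0.1–0.3` is the usual working range; smaller values starve the
counts (SampEn NaNs), larger values saturate them.

## Preprocessing

Band-pass 4–40 Hz, 5th-order Butterworth, applied forward–backward
(zero phase): ERD/S is time-locked to the cue, so group delay would bias
latencies; the effective magnitude response is squared. Epochs are
filtered directly with odd-reflection padding. The spatial filter is the
small surface Laplacian — each channel minus the mean of its 4 nearest
montage neighbors (adjacency configurable, so large-Laplacian variants
are possible) — which cancels spatially smooth volume-conducted
activity. Time is measured in seconds from trial start and all intervals
are half-open `[t0, t1)`.

## Synthetic data

Each trial is 1/f background noise (spectrally shaped white noise, unit
variance, per channel) plus a mu-band sinusoid (random phase, ±20 %
amplitude jitter) on the two sensorimotor channels; on the channel
contralateral to the imagined hand the mu amplitude is multiplied by
`1 − erd_depth` inside the ERD interval with 0.25 s raised-cosine ramps.
Defaults: 250 Hz, 7 s trials, cue at 2 s, ERD interval [2.5, 4.5] s,
`erd_depth = 0.6`, mu-to-noise amplitude ratio `snr = 2`, balanced
left/right labels, fully reproducible from the seed. The 22-channel
layout of the standard four-class MI benchmark is built in (C3 = channel
8, C4 = channel 12, numeric labels elsewhere, so the sensorimotor groups
left {C3, 9, 14, 15}, right {C4, 11, 18, 17} and midline {10, 16} are
addressable); other channel counts place the C3/C4 analogues over the
hand areas with filler channels on a ring.

Volume conduction (`mixing_strength > 0`) does two things, both scaled
by the one parameter: channels are mixed by a row-normalized Gaussian
distance-kernel matrix, and a spatially smooth mu-band oscillation from
a distant posterior source (no task modulation) is superimposed. The
second component is deliberate: linear mixing of channel-independent
broadband noise barely affects band-power ratios and cannot mask the
ERD, whereas an in-band distant rhythm does — and is exactly what a
surface Laplacian removes. This reproduces, as a testable inequality,
the observation that the contra-vs-ipsi mu-power contrast grows after
Laplacian filtering of volume-conducted data.

What the generator does *not* emulate: realistic forward-model head
geometry, ocular/muscular artifacts, non-stationary background spectra,
inter-subject variability, or any relation between entropy and brain
state beyond the amplitude mechanism above. Passing tests therefore show
that the estimators and analyses behave correctly for
amplitude-modulated oscillations in 1/f noise — the accepted ERD
mechanism — not that they will attain any particular accuracy on real
recordings.

## Analyses

- **Features**: per-trial entropy courses restricted to the MI interval,
  concatenated over channels and windows; NaN cells imputed by the
  per-feature median.
- **Classification**: LDA under stratified 10-fold cross-validation
  (shuffled folds, fixed seed), accuracy reported as mean ± sd on the
  0–100 scale.
- **Grid tuning**: exhaustive evaluation of τ ∈ {1, 1.5, 2} s ×
  M ∈ {1, 2, 3} × ρ ∈ {0.05, 0.1, …, 0.9} (90 configurations); ties in
  mean accuracy resolve toward the simpler model (smaller M, then ρ,
  then τ). For VQEnt the median codebook size at the selected
  configuration is reported as a diagnostic.
- **Trial similarity**: `d(n,n′) = exp(−‖H_n − H_n′‖²/σ²_X)` between two
  estimators' single-trial courses on one channel, with `σ²_X` the
  course-vector variance pooled over both estimators' trial sets; the
  upper/lower triangles hold right/left-label pairs respectively.
- **Channel relevance**: Euclidean distance between the class-mean
  entropy courses per channel; the incremental-accuracy curve re-fits
  the classifier on the top-k channels, optionally restricted to the ten
  sensorimotor channels.
- **Cluster permutation test**: per channel × window two-sample t
  statistic; cells beyond the two-sided critical value at the
  cluster-forming level (default 0.02) are clustered over temporal and
  montage adjacency; cluster mass (summed t) is referred to the
  permutation null of the maximum cluster mass (implementation:
  `mne.stats.spatio_temporal_cluster_test` with our t statistic,
  threshold, adjacency and seed). P-values are familywise corrected by
  construction.

## Problem sizes and numerical checks

The test suite and `scripts/acceptance.py` run on synthetic sets sized
for a single core: 50 trials/class for the physiological-pattern and
power-recovery checks, 25/class for classification and channel
reduction, 10/class across 20 seeds for relevance recovery, 16-trial
null datasets (500 permutations each, 200 replicates) for the
calibration of the cluster test, and 6/class with 2 channels for the
90-configuration tuning grid. The sample-entropy oracle is a literal
O(Q²) double loop; the analytic white-noise reference is
`−ln erf(ρ/2)`, the independence limit of the per-coordinate match
probability for i.i.d. Gaussian samples.

## Known limitations

- The VQ codebook is order-dependent (online greedy): permuting the
  delay vectors can change `Q′` by a few codes. Deterministic for a
  given window, which is what reproducibility requires.
- SampEn can be undefined (NaN) for small ρ or short windows; the
  pipeline handles this but tuning grids over ρ = 0.05 routinely hit it.
- The entropy–amplitude coupling relies on the fixed (trial-level)
  tolerance; with per-window tolerances the estimators measure waveform
  regularity only and the ERD dip is not expected.
- EDF/GDF reading delegates to `mne` and epochs strictly by annotation
  codes; artifact-annotation handling beyond dropping unlabeled trials
  is out of scope.
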