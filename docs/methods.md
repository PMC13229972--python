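# Methods

This note records the model, the numerical conventions, and the design
choices behind `eeglrtc`, including the points where the analysis recipe is
genuinely open and the package had to fix a convention.

## Signal model and assumptions

Input recordings are assumed artifact-cleaned multichannel EEG
(channels × samples, known sampling rate). The analysis targets the
alpha band (8–13 Hz) and assumes that the informative structure is the slow
modulation of alpha power, observed through n non-overlapping windows. The
embedding step assumes those n feature vectors sample a connected,
low-dimensional manifold densely enough for a k-NN graph to approximate its
geodesics. DFA itself tolerates nonstationarity in the window series — its
local detrending removes slow trends segment by segment — but the scaling
exponent is only interpretable as LRTC while 0.5 < α < 1.

## Feature extraction

- **z-scoring**: per channel over the full analyzed segment (per condition),
  sample SD with n−1 denominator. A constant channel is an error, not a
  silent drop; faulty channels are removed only via an explicit exclusion
  list, never auto-detected, to keep runs reproducible.
- **Band-pass**: order-4 Butterworth applied forward–backward
  (`sosfiltfilt`), i.e. zero-phase and effectively order 8. Chosen as the
  standard EEG practice that does not distort envelope timing; the exact
  filter family is a free choice and is not load-bearing for the scaling
  exponent.
- **Band power**: one modified periodogram per 2-s window with a Hamming
  taper spanning the whole window, integrated over 8–13 Hz (bin endpoints
  inclusive) by the trapezoidal rule. A 2-s window gives 0.5 Hz bins, so the
  band holds 11 bins. Single-window PSD estimators differ in whether they
  average sub-segments; the single-taper whole-window convention is used
  because it is the default behavior of the common built-in band-power
  routines and is deterministic at fixed input.

## Embedding

- **k selection**: k₀ = ⌈√n⌉ (the rounding of √n had to be fixed; ceiling
  matches n = 90 → k₀ = 10), incremented until the OR-symmetrized k-NN graph
  is connected. The search never goes below k₀. Neighbor ties break toward
  the lower index via a stable sort.
- **Geodesics**: Dijkstra on the weighted graph (scipy.sparse.csgraph); a
  disconnected graph is an error instructing the caller to raise k.
- **Classical MDS**: B = −½HG²H is symmetrized (B ← (B+Bᵀ)/2) before
  eigendecomposition to guard against floating-point asymmetry. Negative
  eigenvalues — expected, since geodesic matrices are generally
  non-Euclidean — stay in the reported spectrum but are excluded from
  coordinates and from explained-variance denominators. Eigenvector sign is
  fixed by making each column's largest-magnitude entry positive.
- **PCA baseline**: covariance (not correlation) of column-centered,
  unstandardized features, because the features are all in the same power
  units.
- **Elbow rule**: the reference analysis picks d by visual inspection of the
  eigenvalue spectrum; the automated stand-in takes the discrete second
  difference of log₁₀ of the max-normalized spectrum over positions
  2..min(10, m−1) and returns the dimension just before the curvature
  maximum — the last dimension before the spectrum levels off. A strictly
  geometric decay has zero log-curvature everywhere, so a curvature maximum
  below 0.05 (log₁₀ units) is flagged "no clear elbow" and a configured
  default (3) is returned. The log-scale form was chosen because the plain
  max-normalized second difference is dominated by the first eigenvalue drop
  and cannot produce an elbow beyond position 1 on realistic spectra.
- **Explained variance** for Isomap is the kernel-eigenvalue ratio
  (top-d over all positive eigenvalues of B). Residual-variance definitions
  exist; the kernel ratio is implemented and labeled as such.

## DFA

- Profile Z(k) = Σᵢ≤ₖ(yᵢ − ȳ); scales are **all** integers in
  [4, ⌊n/4⌋] — with n ≈ 90 only 19 scales exist, so log-spacing would
  discard most of the usable grid.
- Detrending order defaults to 1 (DFA-1, the canonical choice), exposed as a
  parameter. Segments are taken forward from the start; the trailing
  remainder at each scale is excluded, and F(p) is the RMS of residuals over
  the covered samples.
- α and R² come from OLS of log₁₀F on log₁₀p (the slope and R² are
  base-invariant). A fit needs ≥ 2 scales (n ≥ 20); fits on < 4 scales are
  flagged `short_series`.
- **Mean-based variant**: DFA per embedding dimension, α and R² averaged
  arithmetically. The reported fluctuation curve is the across-dimension
  mean of F(p), for reporting only — the exponent is the mean of slopes, not
  the slope of the mean. How the mean-based R² should be aggregated is not
  fixed by the reference description; the arithmetic mean was chosen for
  symmetry with α.
- F(p) at consecutive integer scales is stochastically noisy (neighboring
  scales share most segments but differ in remainder handling), so
  monotone growth of F is asserted octave-wise — F(2p) > F(p) — rather than
  step-wise.

## Bootstrap and comparisons

- Moving-block bootstrap resamples **rows of the embedding** in contiguous
  blocks of length max(2, round(√n)) drawn with replacement from all start
  positions, concatenated and truncated to n, recomputing DFA per resample.
  Resampling the embedding rows (rather than the collapsed 1-D series)
  keeps one resampling scheme valid for both DFA variants and preserves
  cross-dimension structure. The CI is the plain 2.5/97.5 percentile
  interval; no bias correction is implied by "95% CI". A resample on which
  DFA fails is redrawn up to 10 times, then the run errors rather than
  silently dropping resamples.
- Paired comparison: two-sided paired t (df = n−1); paired Cohen's d =
  mean(a−b)/sd(a−b) with n−1 denominator; Bonferroni p = min(1, m·p) with
  family size m = 4 by default (two stimuli × two conditions); Wilcoxon
  signed-rank with the classical zero-discard convention, other zero
  policies selectable. All-zero differences short-circuit to t = 0, p = 1,
  d = 0 with a degeneracy flag.

## Synthetic data

The generator emulates the study conditions the analysis is built for: by
default 24 channels, 180 s at 500 Hz, a 3-dimensional latent manifold,
latent Hurst 0.8, 10 Hz carrier, additive sensor noise sd 0.1.

- **fGn** is generated by circulant (Davies–Harte) embedding of the exact
  fGn autocovariance γ(k) = ½(|k+1|²ᴴ − 2|k|²ᴴ + |k−1|²ᴴ): eigenvalues of
  the 2n circulant are obtained by FFT and tiny negative values from
  rounding are clipped (for fGn the embedding is nonnegative-definite across
  H ∈ (0,1) at the sizes used, so the clip is a numerical guard, not an
  approximation in practice). Exactness matters because DFA α ≈ H is the
  module's oracle property. Note that under strong persistence the
  *centered* sample variance of a finite path is biased low
  (E[s²] ≈ γ₀(1 − n^{2H−2})); variance checks use the uncentered mean
  square, which is unbiased for this zero-mean process.
- **Recordings**: envelopes 1 + 0.35·fGn clipped at 0.05 (the clip touches
  ≈ 0.3% of samples, preserving the correlation structure) modulate
  random-phase carriers; channels are tanh of latent combinations with
  seed-fixed weights (scaled by 1/√latent_dim) plus Gaussian noise. The tanh
  guarantees a curved manifold so the nonlinear embedding has an actual
  advantage to demonstrate.
- Not emulated: ocular/muscle artifacts, volume conduction, 1/f broadband
  background, inter-channel noise correlation. Passing tests therefore show
  the *estimator chain* is correct under the stated generative model, not
  that real EEG satisfies that model.

## Problem sizes in tests

The test and acceptance suites run the calibrations at the sizes the method
is meant for: 20 seeds × length 10⁴ for white-noise calibration, 20 × 2¹⁴
for persistent fGn, 100 replications × (n = 512, d = 3) with 200 resamples
for bootstrap coverage, and full-pipeline runs at 16 channels × 180 s ×
200 Hz (n = 90 windows). These sizes make every stochastic check stable
while keeping a full run of the suite inexpensive on a single CPU.

## Known limitations

- The elbow rule is a deterministic stand-in for visual inspection; on
  spectra without a sharp knee it falls back to a configured default rather
  than guessing.
- The moving-block bootstrap preserves short-range dependence but not the
  cross-scale correlation structure DFA exploits, so its intervals can
  understate uncertainty; block length uses the √n heuristic, not a
  data-driven optimum.
- Condition segmentation (which sample ranges belong to which stimulus) must
  be supplied explicitly; the package never infers it from the data.
- DFA exponents are reliable only within the power-law regime; values
  outside (0.5, 1), which the norm-based variant produces more often, should
  be read as instability of that collapse rather than as stronger structure.
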