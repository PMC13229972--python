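# eeglrtc

Long-range temporal correlations (LRTC) in alpha-band EEG, estimated on a
low-dimensional embedding of the multichannel dynamics rather than channel by
channel.

EEG sensor data are high-dimensional but spatially redundant: the underlying
neural dynamics often live on a curved low-dimensional manifold inside the
sensor space. This package implements an analysis framework for researchers
studying scale-free brain dynamics (e.g. under music or other sustained
stimuli): windowed alpha-band (8–13 Hz) power features are embedded with
Isomap (or PCA as a linear baseline), and detrended fluctuation analysis (DFA)
is applied to the embedded trajectory to quantify the persistence of its
temporal correlations.

## Method

1. **Features** — each channel is z-scored, band-passed 8–13 Hz (zero-phase
   Butterworth), and split into non-overlapping 2-s windows (n = ⌊T/L⌋
   windows, 0.5 Hz resolution). Per window and channel, alpha-band power is
   the Hamming-tapered periodogram integrated over 8–13 Hz, giving the
   feature matrix X<sub>α</sub> ∈ ℝ<sup>n×N</sup>.
2. **Embedding** — Isomap: a k-nearest-neighbor graph on the n windows
   (smallest k ≥ ⌈√n⌉ giving a connected graph), geodesic distances by
   Dijkstra, classical MDS on the geodesic matrix
   (B = −½HG²H, Y = V<sub>d</sub>Λ<sub>d</sub><sup>1/2</sup>). Dimensionality
   d comes from an elbow rule on the eigenvalue spectrum; quality is
   summarized by trustworthiness and cumulative explained variance.
3. **DFA** — on the profile Z(k) = Σ<sub>i≤k</sub>(y<sub>i</sub> − ȳ), with
   linear detrending over all integer scales p ∈ [4, ⌊n/4⌋], the exponent α
   is the slope of log F(p) vs log p. α = 0.5 is uncorrelated noise,
   0.5 < α < 1 persistent LRTC. Two variants: **norm-based** (DFA of the
   per-window embedding norm) and **mean-based** (per-dimension DFA, exponents
   averaged — the more stable estimator).
4. **Statistics** — moving-block bootstrap (block length max(2, round(√n)),
   percentile 95% CI) for per-recording uncertainty; paired t-test,
   Bonferroni correction, Wilcoxon signed-rank and paired Cohen's d for
   condition comparisons.

A synthetic-data module generates fractional Gaussian noise by exact
circulant embedding and EEG-like recordings (fGn envelopes modulating ~10 Hz
carriers, tanh-mixed into channels) with known ground-truth Hurst exponents,
so the whole chain is testable without recordings.

## Worked example

```python
from eeglrtc import (SyntheticSpec, generate_recording, RunConfig, run_pipeline)

spec = SyntheticSpec(n_channels=16, duration_s=180.0, fs=200.0,
                     latent_dim=3, latent_hurst=0.8, seed=1)
cfg = RunConfig(method="isomap", approach="mean", n_boot=1000, seed=1)
report = run_pipeline(cfg, recording=generate_recording(spec))
```

This prints (via the report dict): 90 windows, neighborhood size k = 10,
elbow dimension d = 3 — recovering the planted 3-dimensional latent
structure — and

```
alpha = 0.644   R^2 = 0.941   per-dimension alphas = [0.574, 0.628, 0.730]
bootstrap mean = 0.639, 95% CI [0.528, 0.762], block length 9
```

The mean-based exponent sits in the persistent range (0.5, 1), as expected
for a latent Hurst exponent of 0.8 filtered through band-power windowing and
a nonlinear mixture.

Comparing the published per-subject exponent tables (shipped as package
data) between the Isomap and PCA pipelines:

```python
from eeglrtc import alpha_column, paired_comparison
rep = paired_comparison(alpha_column("isomap", "mean", "yaman", "during"),
                        alpha_column("pca", "mean", "yaman", "during"))
# t = 2.581, p = 0.024, Bonferroni p = 0.096, Cohen's d = 0.72
```

i.e. a medium-to-large paired effect of the embedding choice on the
estimated exponent during music listening.

The same operations are available from a shell:

```bash
eeglrtc simulate --channels 16 --duration 180 --fs 200 --hurst 0.8 --seed 1 --out rec.csv
eeglrtc features --in rec.csv --fs 200 --out features.csv
eeglrtc embed --in features.csv --method isomap --out-prefix emb
eeglrtc dfa --in emb_coords.csv --approach mean --out dfa.json
```

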