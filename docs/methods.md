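# Methods notes

This note records the models, conventions, numerical choices, and known
limitations behind `mbcensor`, at the level of detail a maintainer or a
reviewer of results produced with it would need.

## Framewise statistics and filtering

FD at frame t is the sum of absolute backward differences of the six
rigid-body parameters from t−1 to t, with rotations converted to arc
length on a 50 mm radius sphere (1° ≈ 0.8727 mm).  DV is the RMS over
voxels (or ROIs) of the backward temporal difference of the mode-1000
normalized signal.  Element 0 of every framewise series is 0 by
convention: it is not a measurement and is never censorable by itself;
it is excluded from GEV fitting and from pooled-quantile threshold
construction for the same reason.

All filters are digital Butterworth designs applied forward–backward
(zero phase), which squares the single-pass magnitude response: an
order-2 low-pass has gain exactly 0.5 at its cutoff.  The closed-form
gain used by the tests is the bilinear-transform transfer function
1/(1 + (tan(πf/fs)/tan(πfc/fs))^(2n)); at multiband sampling rates this
differs substantially from the analog prototype 1/(1+(f/fc)^(2n)) for
frequencies approaching Nyquist (at fs = 1/0.72 Hz and fc = 0.2 Hz the
0.4 Hz gain is 0.0208, not the analog-limit 1/17 ≈ 0.059).  Edge
handling is reflect padding of length 3·(order+1); run edges are
trimmed later in the pipeline anyway.  Motion parameters are filtered
after equilibration-volume removal.

The default notch band for the notch variants is 0.31–0.43 Hz, with
0.2–0.5 Hz selectable.  Gaussian smoothing for standard DV on volume
data is separable with σ = FWHM/2.3548 per axis (default 4 mm FWHM),
renormalized within the brain mask; smoothed data are used for nothing
else.

## GEV-DV censoring

The run-adaptive threshold censors the right tail of a maximum-
likelihood GEV fit to the run's LPF-DV values, with tail mass
clamp((k_G + 0.3)/d_G, 0, 1).  The shape convention is
heavy-right-tail-positive (the negative of scipy's `genextreme` shape).
The fit standardizes the data, starts from probability-weighted-moments
estimates, and refines by Nelder–Mead on the negative log-likelihood
(tolerance 1e−8); standardization makes location/scale equivariance of
the fit exact up to optimizer arithmetic (verified to 1e−6).  An
unconverged fit falls back to the empirical quantile with k_G treated
as 0, with a logged warning.  Ties at the threshold are kept (strict
inequality flags), a measure-zero choice on real data.

Runs retaining fewer than 167 volumes (2 minutes at TR = 0.72 s) are
excluded; subjects are retained with ≥ 1 surviving run.  Percent
removed uses the pre-exclusion denominator: every frame entering
censoring consideration counts, and flagged frames of later-excluded
runs still count as removed.

## RSFC pipeline

Per run and per series (ROI and nuisance alike): demean and linear
detrend, linear interpolation across censored frames, 0.009–0.08 Hz
band-pass, 30-volume edge trims, then removal of censored frames from
the retained window.  The trend is *fitted on kept frames only* and
evaluated over all frames; combined with interpolation this guarantees
that the content of a censored frame has exactly zero influence on the
output (verified elementwise in the tests).  Edge runs of censored
frames are held at the nearest kept value, since two-sided linear
interpolation is undefined there.

Connectivity is the partial correlation of each ROI pair against the
full nuisance design, computed on retained frames by QR
residualization, Fisher-transformed immediately (|r| clamped at
1 − 1e−12), and averaged (unweighted) over a subject's included runs.
The design contains the band-passed motion parameters, their squares,
their backward-difference derivatives and the squared derivatives (24
columns; squares and derivatives are taken *after* filtering), WM and
CSF signals with derivatives when compartment masks exist, the global
signal with derivative under GSR, and an always-included intercept (29
columns without GSR, 31 with, when all compartments are present).
WM/CSF/GS pass through the same preprocessing path as ROI series so
design and data are spectrally matched.  A series lying in the design
span has residual variance 0; its partial correlations are defined as
0.  Rank-deficient designs raise an error naming the collinear columns.

WM/CSF compartment masks are eroded with a 6-connected structuring
element up to four times, stopping before the mask would empty.  The
mode for mode-1000 normalization is the midpoint of the tallest of 256
histogram bins spanning the 1st–99th intensity percentiles.

## MAC-RSFC

ΔZ_{i,k} averages, over subject i's surviving runs, the difference
between targeted-censoring z and the mean over N_RAND = 10
count-matched random censoring vectors; MAC-RSFC is the grand mean of
|ΔZ_{i,k}|.  Random vectors are seeded per (subject, run, permutation)
so results are independent of iteration order; random-censored
pipelines re-run interpolation/filtering/trimming identically to
targeted ones.  Runs excluded by targeted censoring are excluded from
the random arm.  The statistic decomposes as a mean of per-subject
contributions c_i = mean_k |ΔZ_{i,k}|; the 95% CI is a bias-corrected
and accelerated bootstrap over subjects (B = 10,000 by default,
jackknife acceleration), cross-checked in the tests against an
independent BCa implementation.  MAC-RSFC has a nonzero null
expectation (≈ the sampling noise of the random baseline, shrinking
roughly as 1/√N_RAND), so it compares methods at matched percent
removed and is not used to pick thresholds within a method.

## ΔMSE-RSFC

The sweep realizes percent-removed targets (default 0–80% in 5% steps)
as pooled-statistic quantiles (LPF-FD and the combined fixed-ratio
method) or via the mean GEV tail-mass relation (d_G).  At each grid
point it measures, per pair: ΔBias = −|mean_i ΔZ_{i,k}| (reusing the
MAC-RSFC machinery with the same N_RAND and seed discipline), the
between-subject variance of targeted z (ddof = 1), and N_S.  Curves are
re-parameterized by realized percent removed and linearly resampled to
a 0.01% grid.  The uncensored removable bias per pair is the slope of
−ΔBias vs percent removed, fitted through the origin by IRLS with
bisquare weights (c = 4.685, OLS start, tolerance 1e−8, 50-iteration
cap with OLS fallback), times 100.  The objective combines these per
Bias_c² = Bias_u² + [(Bias_u+ΔBias)² − Bias_u²] and
ΔMSE_k = (σ̂²_c + Bias_c²)/N_S − (σ̂²_u + Bias_u²)/N_SU, averaged over
pairs; it is exactly 0 at 0% removed.  Note that the two-step
squared-bias update collapses algebraically to (Bias_u + ΔBias)² ≥ 0;
a negative-value counter is kept for auditability but cannot trigger
with this estimator.  The optimum is the curve minimum within 0–80%
(excluding the instability near total removal), with the censoring
parameter recovered by inverse interpolation of the percent↔parameter
map.  Combined censoring fixes Φ_F/d_G at a supplied ratio (defaults
0.02438 mm without GSR, 11.0277 mm with, transferred from large-sample
joint optimization) and unions the masks.  The optional 2-D grid search
evaluates the same objective on a (Φ_F, d_G) grid, with Bias_u taken
from a 1-D LPF-FD sweep.

Subjects dropped at stricter grid points leave the mean and variance to
be computed over survivors only.  A sweep truncates when fewer than 3
subjects survive.

## Synthetic-data generator

The generator defines the study conditions for all simulation-based
checks.  Defaults: 40 subjects × 4 runs × 300 frames at TR = 0.72 s,
10 ROIs placed pseudo-randomly in a 70 mm sphere, two-block network
covariance (within-network r = 0.35, between 0.08), white-noise floor
sd 0.5, artifact coupling 3.0.

Motion: per-axis AR(1) drift (φ = 0.98, innovation sd 0.01 mm/°),
respiratory pseudomotion at 0.3 Hz with amplitude 0.2 mm × subject
severity on the phase-encode translation (plus 30% on pitch), and
single-frame spikes (2% of frames, 0.8 mm × severity).  The
respiratory waveform alternates breath depth,
w(θ) = 3 sin(θ/2) + sin(3θ/2)/3, so that the *magnitude* of its
frame-to-frame increments has one bump per cycle and the FD spectrum
genuinely peaks at the respiratory rate — FD rectifies increments, so a
pure sinusoid would place the whole signature at twice the respiratory
frequency, which contradicts what FD traces of respiring subjects show.
Subject severities are gamma(4, 0.25)-distributed (mean 1, CV 0.5),
right-skewed like empirical mean-FD distributions.

Signal: multivariate Gaussian draws from the network covariance plus
white noise; the motion-coupled artifact adds
coupling × ℓ_i × (FD ⊛ 6 s exponential kernel, median-centered) to ROI
i, where the loadings ℓ are one draw of a spatially smooth positive
field (RBF kernel, 60 mm length scale) shared across the dataset, so
the induced covariance inflation decays with inter-ROI distance.
Ground-truth z is the Fisher transform of the artifact-free population
correlation including the noise floor, i.e. exactly what an infinitely
long clean run would estimate.

The confounded cohort gives half of subjects a latent trait that
multiplies motion severity by 3 and adds `trait_effect` to the
measurable ground-truth z of every pair among the first 70% of ROIs
(positive-semidefiniteness restored by eigenvalue clipping).  With
artifact coupling 0, this reproduces the third-variable failure mode of
motion-correlated quality metrics while the signal contains no artifact
whatsoever.

Seed discipline: a single master seed; each stochastic component draws
from `default_rng([master, tag, subject, run])`, so datasets are
bit-identical across calls and any run is reproducible in isolation.

What the generator does **not** emulate: voxel-level geometry and
partial-volume effects, spatially structured thermal noise,
scanner drift nonstationarity, the empirical joint spectrum of true
respiratory motion vs pseudomotion (unknown quantitatively; the
spectral mix here is a stand-in), or session/day effects.  Passing
simulation tests therefore demonstrates the estimators' internal
consistency and their behavior under the stated artifact model, not
performance bounds on any real dataset.  On synthetic cohorts DV is
computed from the ROI-by-time matrix (there is no voxel grid); the
volume-domain DV path (smoothing, masks) is exercised separately on
small image fixtures.

## Problem sizes

Tests and the acceptance script use desk-scale cohorts chosen to make
every phenomenon statistically unambiguous: 40 × 4 × 300 for
parameter-recovery runs (10 replicates), 60 × 4 × 480 for the confound
demonstration, 1e5 draws for GEV consistency, B = 2,000–10,000
bootstrap resamples.  The full suite runs in a few minutes on one CPU.

## Known limitations

- The percent-removed accounting and the trim-then-drop frame ordering
  are documented conventions; other toolchains may count differently.
- The GEV fit needs ≥ 50 finite values; very short runs cannot use
  GEV-DV censoring.
- BCa intervals for ~40 subjects cover at ≈ 93–94% rather than the
  nominal 95% (finite-n behavior of the method itself, matching
  independent implementations).
- The 2-D grid optimizer is exhaustive and coarse by design; it exists
  as a cross-check on the fixed-ratio 1-D procedure, not as a
  production search.
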