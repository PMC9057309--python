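# mbcensor

Volume censoring ("scrubbing") and censoring-parameter optimization for
multiband resting-state fMRI.

Sub-second multiband acquisitions record not only true head motion but
also respiration-linked pseudomotion — factitious displacement,
concentrated on the phase-encode axis, produced by breathing-driven B0
shifts.  Standard framewise displacement (FD) and DVARS (DV) therefore
flag large numbers of frames that carry no artifact, and the classic
quality-control metrics used to tune censoring (QC-FC and relatives)
are confounded by any trait that covaries with both motion and true
connectivity.  `mbcensor` implements, in Python, a full toolkit for
this problem:

- **Filtered framewise statistics** — LPF-FD / LPF-DV (motion
  parameters or voxel series low-pass filtered at 0.2 Hz with an
  order-2 zero-phase Butterworth filter before differencing) and
  notch-filtered variants (0.31–0.43 Hz or 0.2–0.5 Hz stopbands).
- **Run-adaptive GEV-DV censoring** — fit a generalized extreme value
  distribution to each run's LPF-DV by maximum likelihood and censor
  the right tail of mass (k_G + 0.3) / d_G, where k_G is the fitted
  shape and d_G one dataset-wide aggressiveness parameter: runs with
  heavier DV tails lose proportionally more frames.
- **RSFC pipeline** — mode-1000 normalization, demean/detrend, linear
  interpolation over censored frames, 0.009–0.08 Hz band-pass, 30-volume
  edge trims, partial correlations of every ROI pair against a nuisance
  design (band-passed motion parameters, squares, derivatives, squared
  derivatives, WM/CSF and optionally global signal with derivatives),
  Fisher r-to-z, run averaging; 167-volume run and ≥1-run subject
  retention rules.
- **MAC-RSFC** — for subject i and pair k,

  ΔZ_{i,k} = (1/N_Ri) Σ_j [ Z_{i,j,k} − (1/N_RAND) Σ_p Z_RAND_{i,j,k,p} ],
  MAC-RSFC = mean_{i,k} |ΔZ_{i,k}|,

  the mean absolute change in connectivity due to targeted censoring
  over and above count-matched random censoring (N_RAND = 10), with BCa
  bootstrap CIs over subjects.
- **ΔMSE-RSFC optimization** — the bias–variance objective

  ΔMSE_k = [σ̂²(θ̂_ck) + Bias(θ̂_ck,θ_k)²]/N_S − [σ̂²(θ̂_uk) + Bias(θ̂_uk,θ_k)²]/N_SU,

  averaged over pairs, where ΔBias at each sweep point is
  −|mean_i ΔZ_{i,k}| and the uncensored bias is extrapolated to 100%
  frames removed by a zero-intercept robust (bisquare, c = 4.685)
  regression on percent removed after resampling every curve to a
  0.01% grid.  Minimizing over the 0–80% range yields the optimal
  Φ_F (LPF-FD threshold) or d_G, a fixed-ratio combined Φ_F/d_G sweep,
  or an optional 2-D grid search.
- **Classic DQMs for comparison** — QC-FC, median absolute QC-FC, FDR
  null rejection rate, QC-FC distance correlation, high–low tercile
  rejection rates, two-step GLM summaries, between-subject variance
  change — together with a synthetic "third-variable" cohort that
  demonstrates their confounding.
- **Synthetic-data generator** — multi-subject, multi-run motion traces
  (AR(1) drift + ~0.3 Hz respiratory pseudomotion + spikes) and ROI
  timeseries with known network covariance plus a distance-dependent,
  motion-coupled artifact, so every method is testable against ground
  truth without any data download.

## Worked example

`examples/06_optimize_censoring.py` simulates a 40-subject cohort
(4 runs × 300 frames at TR = 0.72 s) with motion-coupled artifact and
optimizes LPF-FD censoring:

```
optimum: 4.98% frames removed (Phi_F = 0.1681 mm), DeltaMSE = -4.293e-05
truth-referenced group MSE: 0.00849 uncensored -> 0.00641 at the optimum (25% lower)
```

The optimizer sees only estimable quantities (between-subject variance,
targeted-vs-random bias change, retained subject count); the last line
checks the selected threshold against the generator's known ground
truth, which the optimizer never touches.

`examples/04_confounded_quality_metrics.py` shows why subject-motion
based metrics cannot be optimization targets.  With **zero** artifact
injected, a latent trait raising both motion and true connectivity
yields:

```
QC-FC null rejection rate (FDR alpha=0.05): 0.289
high-low tercile rejection rate (alpha=0.05): 0.400
```

Both sit far above the nominal 0.05 although there is no artifact to
remove — these metrics reward removing true trait-related connectivity
differences.  The other examples cover simulation (`01`), framewise
statistics and GEV-DV censor plans (`02`), the RSFC pipeline (`03`),
and MAC-RSFC (`05`).

## Command line

A thin CLI wraps the library for shell use:

```sh
mbcensor simulate --seed 7 --out data/
mbcensor censor --manifest data/manifest.tsv --phi-f 0.0318 --dg 1.16 --out plan.json
mbcensor rsfc --manifest data/manifest.tsv --plan plan.json --out rsfc.tsv
mbcensor optimize --manifest data/manifest.tsv --method lpf-fd --out optim.json
mbcensor demo --seed 7          # end-to-end workflow on synthetic data
```

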