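# Methods

## The analysis

`emoplsc` implements a componential-emotion brain–behavior analysis built
around partial least squares correlation (PLSC).  The behavioral block
`Y` (M observations × N = 34 features: 32 GRID questionnaire items rated
1–7 per emotional movie event, plus event-mean heart rate and respiration
rate) and the brain block `X` (M × V per-event contrast maps) are each
normalized to within-subject z-scores.  Their cross-product `R = YᵀX` is
decomposed by SVD, `R = U Δ Wᵀ`, pairing behavior saliences (columns of U)
with voxel saliences (columns of W).  Latent variable k carries a fraction
`δ_k² / Σ δ²` of the total cross-block covariance; latent scores are the
projections `Lx = XW`, `Ly = YU`, and the decomposition guarantees
`LyᵀLx = diag(δ)`.

`R` is kept as the raw cross-product rather than `YᵀX / M` or a
correlation: the scale cancels in saliences, covariance fractions,
permutation p-values, and stability ratios, so the choice is cosmetic; it
is documented here because descriptions of the method sometimes call `R` a
correlation matrix.

### Significance

Latent variables are tested by permuting the rows of Y relative to X
(default 1,000 iterations) and comparing each observed singular value
against its same-rank permutation distribution, with the +1-corrected
p-value `p_k = (1 + #{δ*_k ≥ δ_k}) / (1 + n)`.  Two refinements matter in
practice:

- **Retention is sequential.**  The per-rank null is only calibrated for
  the leading ranks: once the true signal rank is passed, the observed
  spectrum consists of noise singular values occupying *earlier* ranks
  than the same noise occupies in a fully permuted spectrum, which makes
  deep-tail per-rank p-values anti-conservative.  The headline count
  (`PermutationReport.n_retained`) therefore walks down the spectrum and
  stops at the first non-significant component.  Raw per-component flags
  remain available.
- **Alternatives.**  A within-subject permutation scheme
  (`scheme="within_subject"`) and a max-statistic null (`statistic="max"`,
  strong family-wise control, conservative when the data blocks carry
  strong marginal structure) are provided.

### Reliability

Bootstrap stability follows a conservative subject-subsampling design:
each of 1,000 iterations re-fits PLSC on 14 of 20 subjects drawn without
replacement (70%), Procrustes-rotates the re-fit saliences onto the
full-sample model (resampling can rotate and reflect axes), and
accumulates elementwise means and spreads.  The stability score of a
salience element is the full-sample loading divided by its bootstrap
standard error; |S| > 2.5 is treated as reliable (≈ p < 0.01).

Two estimator details are documented because they change the calibration
of that threshold:

- **Finite-population correction (default on).**  m-of-n subsets share
  most of the sample, so their spread understates the full-sample
  standard error by `sqrt(m(n−1)/(n(n−m)))` ≈ 1.49 for 14 of 20.  Without
  the correction the |S| > 2.5 rule flags ~10% of truly-zero saliences;
  with it the bootstrap SE matches the Monte-Carlo sampling SD of the
  estimator.
- **Alignment mode.**  Procrustes alignment absorbs the rotational
  scatter of weakly separated components into the alignment itself, so
  the resulting SE excludes rotational uncertainty that the full-sample
  loading still carries; elementwise false-flag rates on truly-zero
  saliences remain ~10–15% even at high SNR.  `align="signs"` matches
  per-component signs only, keeps rotational scatter in the SE, and
  yields nominal (< 5%) false-flag rates.  The default stays
  `"procrustes"`, matching the published convention; support-recovery
  tests use `"signs"`.

Subject-level K-fold cross-validation (`kfold_cv`) reports held-out
latent-score correlations per LV with a permutation baseline; it is a
generic design, provided for generalizability checks.

## Synthetic study generator

No restricted study data ships with the package; every analysis stage is
exercised on a generator whose ground truth is known exactly.

**Design.**  20 subjects × 4 sessions × 10 videos per session, 1–4 rated
events per video (12 s, non-overlapping, 30 s washout per run, runs of 82
volumes at TR = 2 s).  Session event totals are fixed at (34, 15, 35, 35),
allocated deterministically round-robin over each session's videos; each
of the 10 emotion categories lands on exactly 4 videos via a rotating
assignment.  Subject 1 misses session 1 and subject 2 misses sessions 3–4,
leaving exactly 2,276 observations.  Only the totals and the missingness
pattern are externally constrained; the per-session allocation is one
documented choice among several consistent with them.

**Cross-covariance planting.**  A K = 6 latent vector per observation
drives both blocks: `y = U_true t + subject_offset + ε` and
`x = W_true (g ∘ t) + η` with orthonormal `U_true` (34 × 6) and `W_true`
(V × 6).  Two standardization choices make the planted structure exact
rather than approximate:

- Latent draws are centered and orthonormalized *within each subject*, so
  the realized latent covariance is exactly `diag(c²)` under the same
  normalization the pipeline applies.  In the noiseless limit the
  singular values of `YᵀX/M` equal `c²∘g` exactly.
- Noise variance is balanced per column (feature i receives variance
  `σ² + mean(q) − q_i`, where `q_i` is its planted signal power, floored
  at 0.05) so every column has the same total variance and z-scoring is a
  near-uniform rescale.  Without balancing, the covariance-explained
  spectrum inherits ±1.7-point scatter from the particular salience draw;
  with it, ±0.5.  `balance_noise=False` gives plain homoscedastic noise
  for high-SNR recovery tests.

The six feelings items load only on planted components 1 and 3 (with
elevated weight), so the feelings-only control analysis faces a planted
cross-covariance of rank exactly 2.

**Calibration.**  The default amplitudes `c` (with `g = 1`) were fitted
once by damped multiplicative pilot-simulation updates
(`scripts/calibrate_spectrum.py`) so that the empirical
covariance-explained fractions of the default scenario match
(19.0, 11.0, 6.0, 5.1, 4.6, 3.4) percent; the constants are frozen in the
default configuration and are part of the scenario definition, as is the
default scenario seed.  Held-out scenario seeds reproduce the first
fraction within ±0.9 points.

**Physiology.**  Pulse is a sharp periodic waveform
(`exp(κ(cos 2πφ(t) − 1))`, κ = 20) whose phase integrates an event-driven
rate profile (baseline 72 bpm, per-event plateaus in 64–96 bpm with 3 s
ramps); respiration is a quasi-sinusoid at 12–20 breaths/min.  Traces add
baseline drift, a comb-structured scanner artifact at the slice frequency
17.5 Hz (= 35 slices / 2 s TR) with two harmonics, and white noise.  The
default simulation rate is 500 Hz (any rate ≥ 240 Hz is accepted;
acquisition hardware commonly runs at 5 kHz).  Ground-truth event-window
mean rates are recorded for recovery tests.

**Motion.**  770 runs (20 subjects × 40 runs − 30 missing-session runs)
of smooth random-walk 6-parameter series whose per-frame steps are clipped
so Power FD stays below 0.18 mm for any seed; five documented runs receive
alternating 0.6 mm translation jumps over 19 of 82 frames, guaranteeing
>20% of frames above the 0.5 mm threshold regardless of seed.

**BOLD.**  Per voxel: event regressors (boxcar ⊗ canonical HRF) times
planted betas derived from `W_true` and the event's latent score, plus a
linear drift and AR(1) noise.  Noiseless runs are recovered by the GLM to
machine precision.

**What the generator does not emulate.**  Ratings are continuous by
default (Likert quantization is optional and attenuates loadings); event
labels equal video category; brain maps have no spatial structure,
anatomy, or autocorrelation; physiology has no beat-to-beat variability.
Passing tests demonstrate that the machinery recovers known structure
under these idealized conditions, not that the analysis is robust to every
property of real data.

## Preprocessing stages

**Physiology.**  Traces are anti-alias downsampled to 120 Hz
(polyphase FIR), comb-notched at 17.5 Hz and harmonics (cascaded IIR
notches, Q = 30, zero-phase), band-passed per channel (1–40 Hz cardiac,
0.05–1 Hz respiratory; zero-phase Butterworth, order 4), and converted to
rates by peak detection.  The minimum inter-peak distance is 60/max_rate
(180 bpm cardiac, 60 /min respiratory); the prominence threshold is
`max(MAD, 0.4 × (99.5th percentile − median))` — the second term rejects
band-pass ringing side lobes that a pure MAD scale misses on sharp pulse
trains.  Rates outside 60–100 bpm (HR) are flagged and repaired by
interpolation from in-range neighbors, an automated stand-in for visual
inspection; the corrected fraction is reported so heavy correction is
visible.  Event-mean rates are residualized per subject against six
per-event motion summaries plus intercept (OLS; ridge fallback on rank
deficiency).

**GLM.**  Each run's design holds one boxcar⊗HRF regressor per event
(non-overlapping), one for the washout, six motion nuisance columns, a
discrete-cosine high-pass basis, and an intercept.  The HRF is the
conventional double-gamma (peak 6 s, undershoot 16 s, ratio 6, unit
peak).  The high-pass cutoff 0.004 is interpreted as Hz (250 s period) and
realized as DCT columns inside the model rather than as filtering.  Betas
are plain per-voxel OLS over the whole volume (no mask); pre-whitening is
deliberately omitted.  The event-versus-washout contrast uses weights
(+1, −1).  Framewise displacement: Power (L1 of parameter diffs, rotations
× 50 mm) with threshold 0.5 mm, and Jenkinson (RMS displacement of the
differential rigid transform over an 80 mm sphere) with threshold 0.2 mm;
runs with >20% displaced frames are flagged, reported, and kept unless
dropping is requested.

**Behavior.**  Within-subject z-scores use the population SD (ddof = 0,
configurable); constant within-subject columns map to zero (logged) so
matrix shape is preserved; subjects with a single row are an error.

## Descriptive analyses

Emotion centroids are per-category means of z-scored rows (empty
categories reported, never dropped).  Ward clustering uses scipy's linkage
on the centroid profiles (heights verified against a brute-force
minimum-variance agglomeration oracle).  EFA extracts factors from the
feature correlation matrix by minres (L-BFGS-B over uniquenesses;
principal-axis option), rotates by plain varimax, orders factors by
explained variance, and fixes signs by largest loading; the factor count
uses the Kaiser criterion (eigenvalues > 1, with a 1e−9 numerical guard).
Loading significance is a subject-level bootstrap with Procrustes-aligned
percentile intervals — the published bolding criterion is unexplained, so
this is a documented substitute.  The LV–emotion table is the Pearson
correlation over the 34 features between each centroid profile and each
behavior salience.  The physiology ANOVA is one-way fixed-effects with
`η² = SS_between / SS_total`.

## Numerical conventions

- Sign convention everywhere: the largest-|value| element of each
  behavior salience (or factor loading) is positive; paired vectors flip
  together.  This makes the full pipeline deterministic for fixed input.
- Permutation p-values are +1-corrected and never zero.
- All randomness flows through explicit seeds; identical configuration
  and seed reproduce outputs bit-identically.
- Degenerate inputs: rank-deficient designs fall back to pseudo-inverse
  or ridge with warnings; non-positive-definite correlation matrices are
  eigenvalue-smoothed with a warning; all-zero singular spectra raise.

## Problem sizes

The test suite and the reproduction script run the full default scenario
(M = 2,276, N = 34, V = 2,000) for the PLSC path, the complete 770-run
motion fixture, and reduced sizes elsewhere: V = 200 and 200–300 bootstrap
iterations for resampling property checks, 200 replicates at M = 80 for
permutation calibration, a handful of runs for physiology and BOLD
recovery.  These sizes were chosen so each property is measured with
comfortable Monte-Carlo margins while the whole suite stays desk-scale.

## Known limitations

- The default stability scores inherit the anti-conservatism of
  Procrustes-aligned subsampling described above; use `align="signs"`
  when elementwise false-positive control matters.
- The sequential retention rule is a stopping heuristic, not a
  family-wise-corrected procedure; the max-statistic option provides
  strong control at the cost of power under strong marginal structure.
- K-fold cross-validation is a generic subject-level design; no claim is
  made that it matches any particular published protocol.
- The EFA bolding substitute and the automated rate-gating repair replace
  manual, judgment-based steps of real workflows.
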