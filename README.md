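# emoplsc

Componential-emotion brain–behavior analysis: a tested, reusable pipeline
from event-level emotion ratings, in-scanner physiology, and BOLD runs to
significant, bootstrap-stable latent components linking behavior and brain
activity.

## The problem

Componential theories of emotion hold that an emotional episode engages
several concurrent processes — appraisal, motivation, motor expression,
peripheral physiology, and subjective feeling.  A naturalistic study design
probing this view collects, for every salient movie event, ratings of 32
GRID questionnaire items plus event-mean heart rate (HR) and respiration
rate (RR), alongside a per-event whole-brain contrast map.  The question is
which *coordinated combinations* of behavioral features covary reliably
with distributed brain activity patterns — the functional building blocks
of emotional experience.

`emoplsc` is for researchers who want to run this analysis end to end, or
to validate each stage against synthetic data with known ground truth:
the original study data are access-restricted, so the package ships a
calibrated generator that emulates the study's structure (20 subjects,
40 videos, 119 events over 4 sessions, 2,276 observations after documented
missing sessions) with a planted six-component cross-covariance.

## The method

Both data blocks are normalized to within-subject z-scores: the behavior
block `Y` (M × 34) and the brain block `X` (M × V).  Partial least squares
correlation (PLSC) decomposes their cross-product

```
R = YᵀX = U Δ Wᵀ
```

into paired behavior saliences `U`, voxel saliences `W`, and singular
values `Δ = diag(δ₁ ≥ δ₂ ≥ …)`.  Latent variable (LV) k explains
`δ_k²/Σδ²` of the cross-block covariance; its scores are `Lx = XW`,
`Ly = YU`.  Inference:

- **Significance** — permutation test (1,000 iterations): rows of `Y` are
  permuted against `X`, each observed `δ_k` is compared with its
  permutation distribution, and the leading run of components with
  `p < 0.01` is retained.
- **Reliability** — bootstrap over subjects (14 of 20 without replacement
  per iteration), each re-fit Procrustes-aligned to the full-sample model;
  a salience divided by its bootstrap SE is its stability score, |S| > 2.5
  treated as reliable.
- **Screening** — first-level event GLMs (boxcar ⊗ double-gamma HRF,
  washout baseline, six motion regressors, 0.004 Hz DCT high-pass) produce
  the contrast maps; head motion is screened by Power / Jenkinson
  framewise displacement (0.5 / 0.2 mm, runs with >20% displaced frames
  flagged).
- **Descriptives** — Ward clustering of discrete-emotion centroid
  profiles, exploratory factor analysis (Kaiser criterion, minres,
  varimax), LV–emotion Pearson profiles, physiology ANOVA with η².

See `docs/methods.md` for the full model description, estimator choices,
and known limitations.

## Worked example

Generate the calibrated default scenario and run the PLSC stage:

```python
from emoplsc import assemble_behavior_matrix, fit_plsc, zscore_within_subject
from emoplsc.inference import permutation_test
from emoplsc.synthetic import cpm_default, make_design, make_ground_truth
from emoplsc.synthetic.generate import simulate_brain_maps, simulate_ratings

cfg = cpm_default()
design = make_design(cfg)
truth = make_ground_truth(cfg)
sim = simulate_ratings(design, truth, cfg)
brain = simulate_brain_maps(design, truth, cfg, sim.latents)

Y = zscore_within_subject(assemble_behavior_matrix(sim.ratings, sim.event_physio))
X = zscore_within_subject(brain)
model = fit_plsc(X, Y)
report = permutation_test(X, Y, n=1000, alpha=0.01, seed=1)

print(f"observations: {Y.n_observations}, features: {Y.n_features}, voxels: {X.n_voxels}")
print(f"LVs retained at alpha=0.01: {report.n_retained}")
for k in range(report.n_retained):
    print(f"  LV{k+1}: {100*model.covariance_explained[k]:5.1f}% of covariance, "
          f"p = {report.p_values[k]:.3f}")
```

Output:

```
observations: 2276, features: 34, voxels: 2000
LVs retained at alpha=0.01: 6
  LV1:  19.0% of covariance, p = 0.001
  LV2:  10.9% of covariance, p = 0.001
  LV3:   5.9% of covariance, p = 0.001
  LV4:   5.3% of covariance, p = 0.001
  LV5:   4.7% of covariance, p = 0.001
  LV6:   3.2% of covariance, p = 0.001
```

Six latent variables survive the permutation test; the first pairs a
valence-like behavioral profile with its brain pattern and carries 19% of
the cross-block covariance.  Restricting `Y` to the six feelings items
(`emoplsc.subset_plsc`) leaves only two significant LVs — the classic
valence/arousal picture — showing what the full componential feature set
adds.

The same stages are available from the shell:

```bash
emoplsc simulate --out study/          # ratings, maps, motion, physio, truth
emoplsc glm --motion-dir study/motion --out fd.tsv
emoplsc run --out results/             # full pipeline with default config
```

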