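# Methods

## The analysis model

The pipeline treats each lesion, TMS site, or DBS field as a causal
perturbation of a brain circuit and asks which circuit, when perturbed,
moves a clinical outcome.  Its core assumptions:

* **Common space.** All volumes in one analysis share a voxel grid in a
  standard millimetre space; the NIfTI affine is authoritative, voxel
  indices are 0-based, and a grid mismatch is a hard error (no silent
  resampling).  Non-finite voxels are forced outside the analysis mask at
  construction, so NaNs cannot reach a correlation.
* **Normative connectome as wiring diagram.** A site's circuit engagement
  is summarized by its seed map in an independent multi-subject
  resting-state dataset: per subject, Pearson r between the site's
  weight-averaged timecourse and every in-mask voxel, clipped at
  1 − 1e−7, Fisher z-transformed, then averaged across subjects.
  Clipping keeps z finite for degenerate perfect correlations; averaging
  z rather than r is the standard variance-stabilized choice.
* **As-if-random site placement.** The causal claim rests on site location
  being independent of pre-existing outcome levels.  The synthetic
  generator enforces this by construction; in real data it is an
  assumption, not a theorem.
* **Partial correlation as the mapping statistic.** At each voxel the
  circuit map holds the partial Pearson correlation across patients
  between connectivity z and outcome, controlling for covariates by OLS
  residualization with an intercept.  This is algebraically identical to
  the precision-matrix definition, which the tests use as an independent
  oracle (agreement to 1e−10 on random instances).
* **Covariate policy.** Stimulation cohorts control for change in
  depression and baseline anxiety severity; lesion cohorts for depression
  severity and lesion size; DBS validation additionally for baseline
  depression.  All sets are overridable per dataset.

## Perturbation models

* **TMS**: a decaying sphere, weight `max(0, 1 − d/r_max)` with
  `r_max = 12 mm`.  The decay law inside the sphere is not pinned down by
  the convention the field uses ("decaying sphere"), so the simplest
  monotone profile with compact support — linear to zero at the maximal
  radius — is implemented as one swappable function; alternatives change
  weights, not pipeline structure.
* **Lesions**: binary masks; the voxel count is recorded and used as the
  lesion-size covariate.
* **DBS**: bilateral binary field pairs, never merged into one seed.  Two
  disjoint deep fields have no meaningful joint timecourse, so DBS
  cohorts are scored by overlap (mean circuit value under the left field
  plus mean under the right; an empty hemifield contributes 0) and serve
  as out-of-sample validation rather than circuit derivation.

## Inference

Permutation tests reassign each patient's (outcome, covariates) tuple to
a different patient's imaging, independently within each dataset, then
rebuild every circuit map and the downstream statistic.  Shuffling the
whole tuple preserves within-dataset covariate structure; shuffling never
crosses datasets because outcome scales differ between cohorts.  Design
choices:

* **Add-one p-values**: p = (1 + #{null ≥ observed}) / (1 + N).  Never
  exactly zero, slightly conservative, one-sided ("stronger than
  chance").
* **FWE peaks**: the null statistic is the maximum in-mask voxel of each
  rebuilt combined map (max-statistic correction).  The observed
  statistic is the combined-map value at the queried coordinate, or the
  map's own in-mask maximum when no coordinate is given — the latter is
  the exchangeable "real peak vs permuted peak" comparison, and is what
  makes the null p distribution uniform.
* **Clusters**: connected components at 26-connectivity with
  value-weighted centres of gravity, a generic reimplementation of the
  usual cluster tooling.
* **Seeds**: every stochastic operation takes an explicit recorded seed;
  identical seeds give bitwise-identical null samples.

The within-circuit connectivity score (used to relate a subject's own
connectivity *inside* the circuit to outcome, independent of stimulation
site) takes the top 10% positive and top 10% most-negative circuit voxels
and returns mean pairwise Fisher z within the positive pole, plus within
the negative pole, minus between poles.  Poles are uniformly subsampled
to at most 500 voxels (seeded) to bound the pairwise cost; the score is
symmetric under negating the circuit.  The exact historical definition of
this score varies across prior work, so it is exposed as one named,
swappable function.

## The synthetic generator

`SyntheticSpec` defaults define the reference study conditions:

| parameter | default | meaning |
|---|---|---|
| `grid_shape` / `voxel_size_mm` | 16³ / 2 mm | desk-scale analysis grid; spherical mask of radius 0.9 × half-extent (~1 570 voxels) |
| `n_subjects` / `n_timepoints` | 10 / 120 | connectome size; enough for stable subject-mean z at this grid |
| `smoothness_mm` | 3 | Gaussian sigma of the spatial autocorrelation of connectome noise |
| `circuit_peaks` | ±1 Gaussians (width 5 mm) at (6,6,6) and (−6,−6,−6) mm | planted two-pole circuit, max abs value normalized to 1 |
| `latent_strength` | 1.0 | loading of the shared latent on the circuit |
| `effect_beta` | 0.5 | site-engagement → anxiety effect (in SD units of the standardized true score) |
| `confound_rho` | 0.53 | target anxiety–depression correlation |
| `noise_sigma` | 1.0 | outcome noise SD |
| `n_patients` | 100 | cohort size |

Connectome subjects are smoothed white noise (rescaled to unit voxel
variance) plus `latent_strength · circuit(v) · u(t)` with a shared
standard-normal latent `u`, so the circuit's positive and negative poles
are mutually anticorrelated and seed maps of circuit-adjacent sites
resemble the circuit.

Cohort outcomes follow
`anxiety = effect_beta · s̃ + c · d + ε`, where `s̃` is the standardized
*noiseless* circuit engagement of the patient's site, `d ~ N(0,1)` is the
latent depression confound (recorded as the depression score), and
`ε ~ N(0, noise_sigma²)`.  Two deliberate choices:

* The true score `s̃` comes from the model covariance, not a
  finite-sample seed map: the smoothing operator is applied analytically
  (`G Gᵀ w` by double filtering) and combined with the latent loadings,
  so generation truth is separated from estimation error and recovery
  targets measure the pipeline, not the generator.
* The depression coefficient is solved in closed form,
  `c = ρ · sqrt((β² + σ²) / (1 − ρ²))`, so that the *population*
  correlation between anxiety and recorded depression equals
  `confound_rho` exactly for any effect size.  (Fixing the coefficient at
  ρ and adding measurement noise to depression cannot reach a target of
  0.53 once β and σ are non-trivial, so the coefficient is the calibrated
  quantity.)

Sites are placed uniformly at random: lesions as 3–10-voxel blobs
anywhere in the mask, TMS centres on the outer 30% radial shell (a
cortical-surface stand-in), DBS pairs as ~2.6 mm binary spheres at a deep
left-hemisphere location and its exact midline mirror.  The
individualized-TMS modality assigns each patient one connectome subject
(round-robin) and computes the seed map from that subject alone; site
locations still vary, which departs from a fixed-coordinate
individualized design but keeps a single ground-truth score definition
for all seed-based modalities.

What the generator does **not** emulate: realistic lesion anatomy
(vascular territories, white-matter involvement), BOLD physiology and
preprocessing artefacts, scanner/site effects, non-Gaussian outcome
scales, missing data, and any dependence of site placement on the
patient's pre-existing state.  Passing tests therefore demonstrate that
the estimator and inference machinery are correct and calibrated under
the assumed causal model at desk scale — not that the clinical effect
sizes would reproduce.

## Numerical choices and degenerate inputs

* Correlations are computed via explicit demeaning and norms and clipped
  into [−1, 1]; voxels with zero residual variance become NaN and are
  masked out (set to 0 inside permutation rebuilds, where a degenerate
  voxel must not poison the max-statistic).
* Grid equality uses absolute tolerance 1e−6 on the affine; world↔voxel
  transforms round-trip to 1e−9.
* `partial_correlation` requires n ≥ k + 3 and raises on collinearity
  (residual norm below 1e−12 of the data scale); the specificity model
  additionally rejects designs with condition number > 1e8.
* VLSM voxels need ≥ 5 lesioned and ≥ 1 spared patient; the default
  minimum lesion count is a guard against single-patient voxels.
* Binary ROIs are z-scored within the mask before spatial-correlation
  scoring so binary and weighted comparators share one scoring path;
  weighted ROIs are used as-is (rescaled to max |value| = 1).  The
  circuit supplied as its own ROI reproduces the circuit's predictive r
  exactly, which the tests assert.
* Binarized-outcome analyses (categorical worsening/improvement) reuse
  the same partial-correlation primitive with a 0/1 outcome
  (point-biserial); thresholds are caller-supplied.
* Subgroup prediction pools per-dataset correlations as an n-weighted
  mean r with a normal-approximation p on the pooled Fisher z; whether to
  average r or z first is a genuinely open convention, and the n-weighted
  r mean matches the combination rule used for circuit maps.

## Problem sizes

The validation suite and `scripts/acceptance.py` run at grid 16³ with
cohorts of 30–300 patients, 200-permutation nulls, and 60–100 replicate
calibration loops — sizes chosen so a full run finishes in a few minutes
on one CPU while leaving Monte-Carlo error well inside the asserted
tolerances.  All replicate counts and seeds are fixed in the code.

## Known limitations

* Permutation rebuilds share the cached patient-by-voxel z matrix, so
  memory grows with cohort size × mask size (float64); very large masks
  would need chunking.
* The max-statistic FWE test is one-sided on positive peaks; negative
  peaks require negating the map.
* Pooled subgroup p-values use a normal approximation rather than a
  permutation null.
* The generator's connectome has one global latent; real connectomes have
  many overlapping networks, so specificity analyses on synthetic data
  are easier than on real data.
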