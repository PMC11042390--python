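# circuitmap

Causal brain-circuit mapping from lesions, TMS sites, and DBS stimulation
fields.

## The problem

Focal brain perturbations — strokes, penetrating injuries, transcranial
magnetic stimulation (TMS), deep brain stimulation (DBS) — are natural
experiments: each one causally manipulates a piece of brain circuitry, and
each patient carries a behavioural outcome (here, a validated anxiety
scale, with depression as the ever-present confound).  Individually these
cohorts are noisy and idiosyncratic; together, mapped into a common
circuit space through a normative functional connectome, they can converge
on circuitry that is *causally* involved in a symptom and therefore a
candidate stimulation target.

`circuitmap` implements that pipeline for researchers in lesion network
mapping and brain-stimulation targeting:

1. **Perturbation models** — binary lesion masks, TMS sites as decaying
   spheres (weight `max(0, 1 − d/12 mm)` around the scalp coordinate), and
   bilateral DBS field pairs kept separate per hemifield.
2. **Seed connectivity** — for each site, the Pearson correlation between
   its weighted seed timecourse and every in-mask voxel, per connectome
   subject, Fisher z-transformed (`z = atanh r`) and averaged over subjects.
3. **Circuit maps** — per cohort, the voxel-wise *partial correlation*
   across patients between connectivity `z(v)` and the anxiety outcome,
   controlling for depression (plus baseline severity for stimulation
   cohorts, lesion size for lesion cohorts):
   `R(v) = corr(resid(z(v) | C), resid(y | C))`.
   Cohort maps combine by weighted mean with sample size as weight.
4. **Inference** — outcome-shuffle permutation tests: each permutation
   reassigns (outcome, covariates) tuples across patients within each
   cohort, rebuilds every map, and recomputes the statistic (spatial
   correlation between groups, mean pairwise cross-correlation, or the
   max-statistic FWE peak value).  p = (1 + #{null ≥ obs}) / (1 + N).
5. **Prediction** — new TMS/lesion sites scored by spatial correlation of
   their connectivity map with the circuit; DBS pairs by overlap (mean
   circuit value under the left field + mean under the right); scores
   related to outcome by partial correlation, benchmarked against ROI
   libraries, and profiled for behavioural specificity.
6. **Synthetic studies** — a generator that plants a ground-truth circuit,
   simulates a spatially autocorrelated multi-subject connectome with
   latent circuit structure, and draws patient cohorts whose outcomes
   follow the assumed causal model (including an anxiety–depression
   confound calibrated to r = 0.53), so the whole pipeline is testable
   end to end without clinical data.

## Worked example

A four-cohort synthetic study (two normative TMS/lesion cohorts, one
individualized-connectivity cohort, one held-out DBS cohort; n = 100
each) on a 16³ grid:

```python
import numpy as np
import circuitmap as cm

spec = cm.SyntheticSpec(n_patients=100, rng_seed=7)
circuit, connectome, datasets = cm.make_study(
    spec, modalities=("tms_scalp", "tms_individualized", "lesion", "dbs"),
    names=["tms", "tms_ind", "lesion", "dbs"])

train = [d for d in datasets if d.name != "dbs"]
combined = cm.weighted_mean_map([cm.circuit_map(d) for d in train])
print("recovery r:", round(cm.spatial_correlation(combined.rmap, circuit), 3))

res = cm.permutation_similarity_test(train, (["tms", "tms_ind"], ["lesion"]),
                                     n_permutations=200, rng_seed=0)
print(f"TMS-vs-lesion similarity: r = {res.observed:.2f}, p = {res.p_value:.4f}")

fwe = cm.peak_fwe_test(train, peak_xyz_mm=(6.0, 6.0, 6.0),
                       n_permutations=200, rng_seed=0)
print(f"FWE peak: observed r = {fwe.observed:.2f}, p_FWE = {fwe.p_value:.4f}")

dbs = datasets[3]
scores = cm.score_dataset(dbs, combined)
r, p, n = cm.predict_outcome_change(scores, dbs)
print(f"held-out DBS prediction: r = {r:.2f}, p = {p:.2g}, n = {n}")
```

Output:

```
recovery r: 0.899
TMS-vs-lesion similarity: r = 0.93, p = 0.0050
FWE peak: observed r = 0.50, p_FWE = 0.0050
held-out DBS prediction: r = 0.50, p = 2e-07, n = 100
```

Reading these numbers: the combined circuit map correlates r = 0.90 with
the planted ground truth; the TMS-derived and lesion-derived maps are more
similar than any of 200 outcome-shuffled rebuilds (p = 1/201, the smallest
value 200 permutations can give); the planted peak survives whole-brain
FWE correction; and overlap with the circuit predicts anxiety change in
the DBS cohort that never contributed to the circuit — the out-of-sample
validation the method is designed for.

## Command line

`circuitmap simulate` writes a complete study directory (NIfTI volumes,
cohort CSVs, a checksummed JSON manifest); `map`, `combine`, `compare`,
`peaks`, `score-tms`, `score-dbs`, `benchmark`, and `specificity` each
wrap one library stage over such a directory.  All stochastic commands
require an explicit `--seed`, and identical config + seed reproduces
byte-identical CSV/JSON outputs.

```bash
circuitmap simulate --out study/ --seed 5 --n-patients 30 \
    --modalities tms_scalp,lesion,dbs
circuitmap map --study study/ --dataset lesion-1 --out lesion_map.nii
circuitmap compare --study study/ --group-a tms_scalp-0 --group-b lesion-1 \
    --permutations 1000 --seed 0 --out compare.json
```

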