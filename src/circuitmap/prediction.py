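"""Scoring stimulation sites against a circuit and predicting outcomes.

Two scoring paths, one per modality family:

* TMS / lesion sites carry a whole-brain connectivity map, scored by its
  spatial correlation with the circuit map.
* Bilateral DBS fields are scored by overlap: the mean circuit value under
  the left field plus the mean under the right field (an empty hemifield
  contributes zero).

Per-patient scores are related to clinical change with partial correlation
(parametric t-transform p).  The same machinery benchmarks arbitrary ROI
comparators and profiles behavioural specificity of a site measure.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .connectivity import ConnectivityMap
from .mapping import (
    CircuitMap,
    CohortDataset,
    Modality,
    leave_one_dataset_out,
    partial_correlation,
    partial_correlation_test,
)
from .stimulation import SiteKind, StimulationSite
from .inference import spatial_correlation
from .volumes import BrainVolume, GridMismatchError, VolumeError

__all__ = [
    "ScoreMethod",
    "SiteScore",
    "SpecificityProfile",
    "dbs_overlap_score",
    "predict_outcome_change",
    "roi_benchmark",
    "score_dataset",
    "site_connectivity_score",
    "specificity_profile",
    "subgroup_prediction",
]


class ScoreMethod(str, enum.Enum):
    SPATIAL_CORR = "spatial_corr"
    OVERLAP = "overlap"


@dataclasses.dataclass
class SiteScore:
    patient_id: str
    score: float
    method: ScoreMethod
    circuit_provenance: list

    def __post_init__(self) -> None:
        self.method = ScoreMethod(self.method)
        if not np.isfinite(self.score):
            raise ValueError(f"patient {self.patient_id}: non-finite score")
        if self.method is ScoreMethod.SPATIAL_CORR and abs(self.score) > 1.0 + 1e-9:
            raise ValueError("spatial-correlation scores must lie in [-1, 1]")


@dataclasses.dataclass
class SpecificityProfile:
    """Per-measure partial correlations of a site measure, ranked by |r|."""

    measures: dict        # name -> (partial r, p, n)
    primary_measure: str
    rank_of_primary: int
    model_params: dict    # standardised coefficients of the joint linear model


def site_connectivity_score(conn_map: ConnectivityMap, circuit: CircuitMap,
                            mask: BrainVolume | None = None,
                            patient_id: str = "") -> SiteScore:
    """Spatial correlation of a site's connectivity map with the circuit."""
    score = spatial_correlation(conn_map.zmap, circuit.rmap, mask)
    return SiteScore(patient_id=patient_id, score=score,
                     method=ScoreMethod.SPATIAL_CORR,
                     circuit_provenance=list(circuit.provenance))


def _hemifield_mean(field: BrainVolume | None, circuit: CircuitMap) -> tuple[float, int]:
    if field is None:
        return 0.0, 0
    if field.grid != circuit.rmap.grid:
        raise GridMismatchError("DBS field grid does not match circuit grid")
    sel = (field.data > 0) & field.brain_mask & circuit.rmap.brain_mask
    n = int(sel.sum())
    if n == 0:
        return 0.0, 0
    return float(circuit.rmap.data[sel].mean()), n


def dbs_overlap_score(site: StimulationSite, circuit: CircuitMap,
                      patient_id: str = "") -> SiteScore:
    """Overlap of a bilateral DBS pair with the circuit.

    Score = mean circuit value under the left field + mean under the right
    field.  An empty hemifield (or one wholly outside the mask) contributes
    0; both empty is an error.
    """
    if site.kind is not SiteKind.DBS_PAIR:
        raise ValueError("dbs_overlap_score requires a dbs_pair site")
    left, n_left = _hemifield_mean(site.weights, circuit)
    right, n_right = _hemifield_mean(site.weights_right, circuit)
    if n_left + n_right == 0:
        raise VolumeError("both DBS hemifields are empty or outside the mask")
    return SiteScore(patient_id=patient_id, score=left + right,
                     method=ScoreMethod.OVERLAP,
                     circuit_provenance=list(circuit.provenance))


def score_dataset(dataset: CohortDataset, circuit: CircuitMap,
                  mask: BrainVolume | None = None) -> list:
    """Score every patient in a dataset against a circuit, by modality."""
    scores = []
    for rec in dataset.records:
        if rec.site.kind is SiteKind.DBS_PAIR:
            scores.append(dbs_overlap_score(rec.site, circuit, patient_id=rec.id))
        else:
            if rec.conn_map is None:
                raise ValueError(f"patient {rec.id}: no connectivity map to score")
            scores.append(site_connectivity_score(rec.conn_map, circuit, mask,
                                                  patient_id=rec.id))
    return scores


def predict_outcome_change(scores, dataset: CohortDataset, covariate_fields=None,
                           outcome_field: str = "anxiety"):
    """Partial correlation of site scores with outcome, given covariates.

    Scores must align 1:1 with the dataset's records (matched by patient
    id).  Returns ``(partial r, two-sided p, n)``.
    """
    if covariate_fields is None:
        covariate_fields = dataset.default_covariates()
    by_id = {s.patient_id: s.score for s in scores}
    if len(by_id) != len(scores):
        raise ValueError("duplicate patient ids in scores")
    try:
        x = np.array([by_id[rec.id] for rec in dataset.records])
    except KeyError as exc:
        raise ValueError(f"score missing for patient {exc.args[0]!r}") from None
    if len(scores) != dataset.n:
        raise ValueError("scores do not align 1:1 with dataset records")
    y = dataset.outcome_vector(outcome_field)
    c = dataset.covariate_matrix(covariate_fields)
    return partial_correlation_test(x, y, c)


# ---- ROI benchmarking ----------------------------------------------------------


def _lodo_circuit(trainable, excluded_name: str, outcome_field: str,
                  covariate_map: dict | None) -> CircuitMap:
    """Leave-one-dataset-out circuit; if the excluded cohort never trains
    the circuit (e.g. a DBS validation cohort), use all trainable cohorts."""
    names = [d.name for d in trainable]
    if excluded_name in names and len(names) > 1:
        return leave_one_dataset_out(trainable, excluded_name, outcome_field,
                                     covariate_map)
    from .mapping import circuit_map as _cm, weighted_mean_map as _wm
    train = [d for d in trainable if d.name != excluded_name]
    if not train:
        raise ValueError("no trainable dataset remains to build a circuit")
    return _wm([_cm(d, outcome_field, (covariate_map or {}).get(d.name))
                for d in train])


def _is_binary(vol: BrainVolume) -> bool:
    vals = vol.masked_values()
    return bool(np.all((vals == 0) | (vals == 1)))


def _roi_as_map(roi: BrainVolume) -> CircuitMap:
    """Wrap an ROI as a scoreable map; binary masks are z-scored in-mask so
    their spatial correlations are well defined and comparable."""
    if not np.any(roi.masked_values() != 0):
        raise VolumeError("empty ROI")
    data = roi.data.astype(float)
    if _is_binary(roi):
        m = roi.brain_mask
        vals = data[m]
        sd = vals.std()
        if sd == 0:
            raise VolumeError("ROI constant within mask")
        data = np.where(m, (data - vals.mean()) / sd, 0.0)
    # scale into [-1, 1] so it satisfies the CircuitMap contract
    peak = np.abs(data[roi.brain_mask]).max()
    data = data / peak if peak > 0 else data
    vol = BrainVolume(grid=roi.grid, data=data, brain_mask=roi.brain_mask)
    return CircuitMap(rmap=vol, weight=1.0, provenance=["roi"])


def roi_benchmark(roi_masks: dict, datasets, outcome_field: str = "anxiety",
                  covariate_map: dict | None = None,
                  include_circuit: bool = True) -> pd.DataFrame:
    """Benchmark ROI comparators against the leave-one-dataset-out circuit.

    For each (ROI, dataset) pair, patients are scored against the ROI with
    the same path used for the circuit (spatial correlation for TMS/lesion,
    overlap for DBS) and the scores are related to outcome by partial
    correlation.  When ``include_circuit`` is set, a ``circuit`` row per
    dataset uses the circuit rebuilt without that dataset.
    """
    datasets = list(datasets)
    trainable = [d for d in datasets
                 if d.modality is not Modality.DBS]
    rows = []
    for ds in datasets:
        cov = (covariate_map or {}).get(ds.name)
        if include_circuit:
            lodo = _lodo_circuit(trainable, ds.name, outcome_field, covariate_map)
            r, p, n = predict_outcome_change(score_dataset(ds, lodo), ds, cov,
                                             outcome_field)
            rows.append({"roi_name": "circuit", "dataset": ds.name,
                         "r": r, "p": p, "n": n})
        for name, roi in roi_masks.items():
            roi_map = _roi_as_map(roi)
            r, p, n = predict_outcome_change(score_dataset(ds, roi_map), ds, cov,
                                             outcome_field)
            rows.append({"roi_name": name, "dataset": ds.name, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)


# ---- specificity ---------------------------------------------------------------


def specificity_profile(site_scores, dataset: CohortDataset, primary: str,
                        controls, covariate_fields=()) -> SpecificityProfile:
    """How specific is a site measure to one behavioural outcome?

    Fits a joint linear model of the site measure on the primary measure
    plus all controls (plus fixed covariates), and computes per-measure
    partial correlations of the site measure with each behavioural measure
    controlling for all the others.  The primary's rank among all measures
    by |partial r| quantifies specificity (rank 1 = most specific).
    """
    controls = list(controls)
    if primary in controls:
        raise ValueError("primary measure listed among controls")
    measures = [primary] + controls
    x = np.asarray([s.score if isinstance(s, SiteScore) else float(s)
                    for s in site_scores], dtype=float)
    if x.size != dataset.n:
        raise ValueError("site scores do not align with dataset records")
    table = {m: dataset.outcome_vector(m) for m in measures}
    covs = dataset.covariate_matrix(covariate_fields)
    design = np.column_stack([table[m] for m in measures] +
                             ([covs] if covs.size else []))
    std = design.std(axis=0)
    if np.any(std == 0):
        raise ValueError("constant predictor in specificity model")
    design_std = (design - design.mean(axis=0)) / std
    if np.linalg.cond(np.column_stack([np.ones(x.size), design_std])) > 1e8:
        raise ValueError("collinear predictors (condition number > 1e8)")
    fit = sm.OLS((x - x.mean()) / x.std(), sm.add_constant(design_std)).fit()
    names = measures + [f"cov_{f}" for f in covariate_fields]
    model_params = dict(zip(names, fit.params[1:]))

    results = {}
    for m in measures:
        others = [table[o] for o in measures if o != m]
        c = np.column_stack(others + ([covs] if covs.size else [])) if (others or covs.size) else None
        results[m] = partial_correlation_test(x, table[m], c)
    order = sorted(measures, key=lambda m: abs(results[m][0]), reverse=True)
    rank = order.index(primary) + 1
    return SpecificityProfile(measures=results, primary_measure=primary,
                              rank_of_primary=rank, model_params=model_params)


# ---- subgroup prediction -------------------------------------------------------


def subgroup_prediction(datasets, grouping_field: str,
                        outcome_field: str = "anxiety",
                        covariate_map: dict | None = None) -> dict:
    """Out-of-sample prediction pooled within binary patient subgroups.

    For each dataset, patients are scored against the leave-one-dataset-out
    circuit; within each level of the (binary) grouping field the score ->
    outcome partial correlation is computed per dataset and pooled as an
    n-weighted mean r (weights follow subgroup sizes).  The pooled p uses
    the normal approximation to the n-weighted Fisher z.
    """
    datasets = list(datasets)
    trainable = [d for d in datasets if d.modality is not Modality.DBS]
    per_group: dict = {}
    for ds in datasets:
        circuit = _lodo_circuit(trainable, ds.name, outcome_field, covariate_map)
        groups = ds.outcome_vector(grouping_field)
        levels = np.unique(groups)
        if not np.all(np.isin(levels, [0.0, 1.0])):
            raise ValueError(f"grouping field {grouping_field!r} must be binary 0/1")
        cov = (covariate_map or {}).get(ds.name) or ds.default_covariates()
        for level in levels:
            idx = [i for i, g in enumerate(groups) if g == level]
            k = len(cov)
            if len(idx) < k + 3:
                continue
            sub = CohortDataset(name=f"{ds.name}|g{int(level)}",
                                modality=ds.modality,
                                records=[ds.records[i] for i in idx])
            scores = score_dataset(sub, circuit)
            r, p, n = predict_outcome_change(scores, sub, cov, outcome_field)
            per_group.setdefault(int(level), []).append(
                {"dataset": ds.name, "r": r, "p": p, "n": n})
    if not per_group:
        raise ValueError("no subgroup was large enough in any dataset")
    pooled = {}
    from scipy import stats as _stats
    for level, rows in per_group.items():
        ns = np.array([row["n"] for row in rows], dtype=float)
        rs = np.array([row["r"] for row in rows])
        pooled_r = float((ns * rs).sum() / ns.sum())
        z = np.arctanh(np.clip(pooled_r, -1 + 1e-12, 1 - 1e-12))
        se = 1.0 / np.sqrt(max(ns.sum() - 3.0 * len(rows), 1.0))
        p = float(2.0 * _stats.norm.sf(abs(z) / se))
        pooled[level] = {"pooled_r": pooled_r, "p": p,
                         "n_total": int(ns.sum()), "per_dataset": rows}
    return pooled
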