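"""Circuit maps: voxel-wise partial correlation of site connectivity vs outcome.

A cohort of patients, each with a whole-brain connectivity map of their
lesion or stimulation site and a clinical outcome, yields a *circuit map*:
at every voxel, the partial correlation across patients between the
connectivity z-value and the outcome, controlling for nuisance covariates
(depression always; baseline severity for stimulation cohorts, lesion size
for lesion cohorts).  Dataset maps are combined by weighted mean with the
dataset sample size as weight.  Partial correlation is computed as the
Pearson correlation of OLS residuals after regressing both variables on an
intercept plus the covariates — textbook-exact, and identical to the
precision-matrix definition.

Also here: voxel lesion symptom mapping (VLSM), the network-free comparator
that correlates the binary per-voxel lesion indicator with outcome.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
from scipy import stats

from .connectivity import ConnectivityMap
from .stimulation import SiteKind, StimulationSite
from .volumes import BrainGrid, BrainVolume, GridMismatchError, VolumeError

__all__ = [
    "DEFAULT_COVARIATES",
    "CircuitMap",
    "CohortDataset",
    "Modality",
    "PatientRecord",
    "circuit_map",
    "leave_one_dataset_out",
    "partial_correlation",
    "partial_correlation_test",
    "unexplained_variance_pct",
    "vlsm_map",
    "weighted_mean_map",
]

_DEGENERATE_TOL = 1e-12


class Modality(str, enum.Enum):
    TMS_SCALP = "tms_scalp"
    TMS_INDIVIDUALIZED = "tms_individualized"
    LESION = "lesion"
    DBS = "dbs"


#: default covariate sets per modality: stimulation cohorts control for
#: change in depression and baseline anxiety severity; lesion cohorts for
#: depression severity and lesion size; DBS validation additionally for
#: baseline depression.
DEFAULT_COVARIATES = {
    Modality.TMS_SCALP: ("depression", "baseline_anxiety"),
    Modality.TMS_INDIVIDUALIZED: ("depression", "baseline_anxiety"),
    Modality.LESION: ("depression", "lesion_size"),
    Modality.DBS: ("depression", "baseline_anxiety", "baseline_depression"),
}


@dataclasses.dataclass
class PatientRecord:
    """One patient: a perturbation site plus outcome and covariate scalars."""

    id: str
    site: StimulationSite
    anxiety: float
    depression: float
    conn_map: ConnectivityMap | None = None
    extra_covariates: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.anxiety) and np.isfinite(self.depression)):
            raise ValueError(f"patient {self.id}: anxiety and depression must be finite")
        if self.site.kind is SiteKind.LESION:
            self.extra_covariates.setdefault("lesion_size", float(self.site.size_voxels))

    def field(self, name: str) -> float:
        """Resolve a named scalar: anxiety, depression, or an extra covariate."""
        if name == "anxiety":
            return float(self.anxiety)
        if name == "depression":
            return float(self.depression)
        try:
            return float(self.extra_covariates[name])
        except KeyError:
            raise KeyError(f"patient {self.id}: unknown field {name!r}") from None


@dataclasses.dataclass
class CohortDataset:
    """One dataset: named cohort of complete-data patients on a shared grid."""

    name: str
    modality: Modality
    records: list

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        if not self.records:
            raise ValueError(f"dataset {self.name!r} has no records")
        grid = self.records[0].site.grid
        for rec in self.records:
            if rec.site.grid != grid:
                raise GridMismatchError(f"dataset {self.name!r}: records on different grids")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def grid(self) -> BrainGrid:
        return self.records[0].site.grid

    def outcome_vector(self, field: str) -> np.ndarray:
        return np.array([rec.field(field) for rec in self.records], dtype=float)

    def covariate_matrix(self, fields) -> np.ndarray:
        fields = tuple(fields)
        if not fields:
            return np.empty((self.n, 0))
        return np.column_stack([self.outcome_vector(f) for f in fields])

    def default_covariates(self) -> tuple:
        return DEFAULT_COVARIATES[self.modality]


@dataclasses.dataclass
class CircuitMap:
    """Voxel-wise partial-correlation map with its combination weight."""

    rmap: BrainVolume
    weight: float
    provenance: list

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("circuit map weight must be positive")
        vals = self.rmap.masked_values()
        if np.any(np.abs(vals) > 1.0 + 1e-9):
            raise VolumeError("circuit map values must lie in [-1, 1]")


# ---- partial correlation -------------------------------------------------------


def _residualize(a: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of each column of ``a`` after OLS on [1, covariates]."""
    n = a.shape[0]
    design = np.column_stack([np.ones(n), covariates]) if covariates.size else np.ones((n, 1))
    q, _ = np.linalg.qr(design)
    return a - q @ (q.T @ a)


def partial_correlation(x, y, covariates=None) -> float:
    """Partial Pearson correlation of x and y given covariates.

    Computed as the correlation of the OLS residuals of x and y after
    regression on an intercept plus the covariate columns.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    c = np.empty((x.size, 0)) if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != x.size:
        c = c.T
    if not (x.size == y.size == c.shape[0]):
        raise ValueError("x, y, and covariates must have the same number of rows")
    k = c.shape[1]
    if x.size < k + 3:
        raise ValueError(f"need n >= {k + 3} observations for {k} covariates, got {x.size}")
    resid = _residualize(np.column_stack([x, y]), c)
    rx, ry = resid[:, 0], resid[:, 1]
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    if sx < _DEGENERATE_TOL * max(1.0, np.linalg.norm(x)) or sx == 0:
        raise ValueError("zero residual variance in x (collinear with covariates?)")
    if sy < _DEGENERATE_TOL * max(1.0, np.linalg.norm(y)) or sy == 0:
        raise ValueError("zero residual variance in y (collinear with covariates?)")
    return float(np.clip(rx @ ry / (sx * sy), -1.0, 1.0))


def partial_correlation_test(x, y, covariates=None):
    """Partial correlation with a parametric two-sided p-value.

    Uses the t-transform t = r * sqrt(df / (1 - r^2)) with df = n - 2 - k
    for k covariates.
    """
    x = np.asarray(x, dtype=float).ravel()
    c = np.empty((x.size, 0)) if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != x.size:
        c = c.T
    r = partial_correlation(x, y, c)
    n = x.size
    df = n - 2 - c.shape[1]
    if df < 1:
        raise ValueError("not enough degrees of freedom for a p-value")
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(r), float(p), int(n)


def partial_correlation_columns(x_cols: np.ndarray, y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Vectorised partial correlation of many columns against one outcome.

    ``x_cols`` is (n, V).  Degenerate columns (zero residual variance) get
    NaN; the caller decides how to mask them.
    """
    resid_x = _residualize(x_cols, covariates)
    resid_y = _residualize(y[:, None], covariates)[:, 0]
    sy = np.linalg.norm(resid_y)
    if sy < _DEGENERATE_TOL:
        raise ValueError("zero residual variance in outcome")
    sx = np.linalg.norm(resid_x, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (resid_x.T @ resid_y) / (sx * sy)
    r[sx < _DEGENERATE_TOL] = np.nan
    return np.clip(r, -1.0, 1.0)


# ---- circuit maps --------------------------------------------------------------


class CohortArrays:
    """Cached design for fast (re-)computation of one dataset's circuit map.

    Extracting the patient-by-voxel connectivity matrix once makes outcome
    -shuffle permutation tests cheap: each permutation only re-residualises
    the shuffled (outcome, covariates) rows against the fixed z matrix.
    """

    def __init__(self, dataset: CohortDataset, outcome_field: str = "anxiety",
                 covariate_fields=None):
        if covariate_fields is None:
            covariate_fields = dataset.default_covariates()
        self.name = dataset.name
        self.weight = float(dataset.n)
        records = dataset.records
        k = len(tuple(covariate_fields))
        if dataset.n < k + 3:
            raise ValueError(
                f"dataset {dataset.name!r}: need at least {k + 3} complete records"
            )
        for rec in records:
            if rec.conn_map is None:
                raise ValueError(f"dataset {dataset.name!r}: patient {rec.id} has no conn_map")
        self.grid = records[0].conn_map.zmap.grid
        mask = records[0].conn_map.zmap.brain_mask.copy()
        for rec in records:
            if rec.conn_map.zmap.grid != self.grid:
                raise GridMismatchError(f"dataset {dataset.name!r}: conn maps on different grids")
            mask &= rec.conn_map.zmap.brain_mask
        if not mask.any():
            raise VolumeError(f"dataset {dataset.name!r}: empty common mask")
        self.mask = mask
        self.z = np.stack([rec.conn_map.zmap.data[mask] for rec in records])
        self.y = dataset.outcome_vector(outcome_field)
        self.c = dataset.covariate_matrix(covariate_fields)
        if np.ptp(self.y) == 0:
            raise ValueError(f"dataset {dataset.name!r}: constant outcome")

    @property
    def n(self) -> int:
        return self.y.size

    def rmap_vector(self, order: np.ndarray | None = None) -> np.ndarray:
        """In-mask partial-correlation vector, optionally with shuffled
        (outcome, covariates) tuples (``order`` permutes patients)."""
        y, c = (self.y, self.c) if order is None else (self.y[order], self.c[order])
        r = partial_correlation_columns(self.z, y, c)
        return np.where(np.isfinite(r), r, 0.0)

    def to_circuit_map(self, r_vec: np.ndarray) -> CircuitMap:
        data = np.zeros(self.grid.shape)
        data[self.mask] = r_vec
        vol = BrainVolume(grid=self.grid, data=data, brain_mask=self.mask)
        return CircuitMap(rmap=vol, weight=self.weight, provenance=[self.name])


def circuit_map(dataset: CohortDataset, outcome_field: str = "anxiety",
                covariate_fields=None) -> CircuitMap:
    """Circuit map of one dataset: voxel-wise partial correlation of
    connectivity z-values against the outcome, given covariates."""
    arrays = CohortArrays(dataset, outcome_field, covariate_fields)
    return arrays.to_circuit_map(arrays.rmap_vector())


def weighted_mean_map(maps, weights=None) -> CircuitMap:
    """Combine circuit maps by weighted mean (weights default to dataset n)."""
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one circuit map")
    if weights is None:
        weights = [m.weight for m in maps]
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(maps) or np.any(weights <= 0):
        raise ValueError("need one positive weight per map")
    grid = maps[0].rmap.grid
    mask = maps[0].rmap.brain_mask.copy()
    for m in maps[1:]:
        if m.rmap.grid != grid:
            raise GridMismatchError("circuit maps on different grids")
        mask &= m.rmap.brain_mask
    acc = np.zeros(grid.shape)
    for m, w in zip(maps, weights):
        acc += w * m.rmap.data
    acc /= weights.sum()
    vol = BrainVolume(grid=grid, data=np.where(mask, acc, 0.0), brain_mask=mask)
    provenance = [name for m in maps for name in m.provenance]
    return CircuitMap(rmap=vol, weight=float(weights.sum()), provenance=provenance)


def leave_one_dataset_out(datasets, excluded: str, outcome_field: str = "anxiety",
                          covariate_map: dict | None = None) -> CircuitMap:
    """Weighted-mean circuit over all datasets except ``excluded``.

    Keeps out-of-sample evaluation honest: the circuit used to score a
    cohort is rebuilt without that cohort.
    """
    datasets = list(datasets)
    names = [d.name for d in datasets]
    if excluded not in names:
        raise KeyError(f"no dataset named {excluded!r} (have {names})")
    rest = [d for d in datasets if d.name != excluded]
    if not rest:
        raise ValueError("no datasets remain after exclusion")
    maps = [
        circuit_map(d, outcome_field, (covariate_map or {}).get(d.name))
        for d in rest
    ]
    return weighted_mean_map(maps)


# ---- VLSM comparator -----------------------------------------------------------


def vlsm_map(dataset: CohortDataset, covariate_fields=None,
             min_lesions_per_voxel: int = 5) -> BrainVolume:
    """Voxel lesion symptom mapping: partial correlation of the binary
    lesioned indicator with outcome, at voxels lesioned in at least
    ``min_lesions_per_voxel`` patients (and spared in at least one)."""
    if any(rec.site.kind is not SiteKind.LESION for rec in dataset.records):
        raise ValueError("vlsm_map requires an all-lesion dataset")
    if covariate_fields is None:
        covariate_fields = dataset.default_covariates()
    grid = dataset.grid
    lesioned = np.stack([
        (rec.site.weights.data > 0).reshape(-1) for rec in dataset.records
    ]).astype(float)
    counts = lesioned.sum(axis=0)
    eligible = (counts >= min_lesions_per_voxel) & (counts <= dataset.n - 1)
    if not eligible.any():
        raise VolumeError(
            f"no voxel lesioned in >= {min_lesions_per_voxel} patients"
        )
    y = dataset.outcome_vector("anxiety")
    c = dataset.covariate_matrix(covariate_fields)
    r = partial_correlation_columns(lesioned[:, eligible], y, c)
    data = np.full(grid.n_voxels, np.nan)
    data[eligible] = r
    mask = eligible & np.isfinite(data)
    return BrainVolume(grid=grid, data=data.reshape(grid.shape),
                       brain_mask=mask.reshape(grid.shape))


def unexplained_variance_pct(r: float) -> float:
    """Percentage of variance left unexplained by a correlation: (1 - r^2) * 100."""
    r = float(r)
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    return (1.0 - r * r) * 100.0
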