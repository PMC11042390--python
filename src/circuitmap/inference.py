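"""Spatial-map inference: correlations, outcome-shuffle permutations, FWE peaks.

The central null model reassigns each patient's (outcome, covariates) tuple
to a different patient's neuroimaging, independently within each dataset,
then rebuilds every circuit map and the derived statistic.  Shuffling the
whole tuple (rather than the outcome alone) preserves the within-dataset
covariate structure and never mixes outcome scales across datasets.

P-values use the add-one estimator p = (1 + #{null >= observed}) /
(1 + n_permutations): one-sided ("stronger than chance"), never exactly
zero, and slightly conservative.  Peak significance is family-wise-error
corrected by the max-statistic null: each permuted map contributes its
maximum in-mask voxel value.
"""

from __future__ import annotations

import dataclasses
import itertools
import json

import numpy as np
from scipy import ndimage

from .mapping import CohortArrays
from .volumes import BrainVolume, GridMismatchError, VolumeError

__all__ = [
    "PermutationResult",
    "cluster_peaks",
    "mean_cross_correlation_test",
    "peak_fwe_test",
    "permutation_similarity_test",
    "spatial_correlation",
]

DEFAULT_N_PERMUTATIONS = 10_000


@dataclasses.dataclass
class PermutationResult:
    """Observed statistic, permutation null sample, and empirical p-value."""

    observed: float
    null_sample: np.ndarray
    p_value: float
    n_permutations: int
    rng_seed: int

    @classmethod
    def from_null(cls, observed: float, null_sample, rng_seed: int) -> "PermutationResult":
        null_sample = np.asarray(null_sample, dtype=float)
        n = null_sample.size
        if n < 1:
            raise ValueError("need at least one permutation")
        p = (1.0 + np.count_nonzero(null_sample >= observed)) / (1.0 + n)
        return cls(observed=float(observed), null_sample=null_sample,
                   p_value=float(p), n_permutations=int(n), rng_seed=int(rng_seed))

    def to_json(self) -> str:
        q = np.quantile(self.null_sample, [0.0, 0.25, 0.5, 0.75, 0.95, 1.0])
        payload = {
            "observed": self.observed,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "rng_seed": self.rng_seed,
            "null_quantiles": {
                "min": q[0], "q25": q[1], "median": q[2],
                "q75": q[3], "q95": q[4], "max": q[5],
            },
        }
        return json.dumps(payload, sort_keys=True)


def spatial_correlation(a: BrainVolume, b: BrainVolume, mask: BrainVolume | None = None,
                        min_voxels: int = 10) -> float:
    """Pearson correlation of two maps over their common in-mask voxels."""
    if a.grid != b.grid:
        raise GridMismatchError("maps on different grids")
    m = a.brain_mask & b.brain_mask
    if mask is not None:
        if mask.grid != a.grid:
            raise GridMismatchError("mask on a different grid")
        m &= mask.brain_mask & (mask.data > 0)
    if m.sum() < min_voxels:
        raise VolumeError(f"fewer than {min_voxels} voxels in the common mask")
    return _pearson(a.data[m], b.data[m])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx, sy = np.linalg.norm(xc), np.linalg.norm(yc)
    if sx == 0 or sy == 0:
        raise VolumeError("constant map in spatial correlation")
    return float(np.clip(xc @ yc / (sx * sy), -1.0, 1.0))


# ---- permutation machinery -----------------------------------------------------


class _StudyPermuter:
    """Shared scaffolding: per-dataset cached designs plus a common mask."""

    def __init__(self, datasets, outcome_field: str, covariate_map: dict | None):
        self.arrays = [
            CohortArrays(d, outcome_field, (covariate_map or {}).get(d.name))
            for d in datasets
        ]
        grid = self.arrays[0].grid
        mask = self.arrays[0].mask.copy()
        for arr in self.arrays[1:]:
            if arr.grid != grid:
                raise GridMismatchError("datasets on different grids")
            mask &= arr.mask
        if not mask.any():
            raise VolumeError("empty common mask across datasets")
        self.grid = grid
        self.mask = mask
        # flat index of the common mask within each dataset's own mask
        self._sub = [mask[arr.mask] for arr in self.arrays]

    def dataset_vectors(self, rng: np.random.Generator | None = None):
        """Per-dataset rmap vectors on the common mask (shuffled if rng given)."""
        out = []
        for arr, sub in zip(self.arrays, self._sub):
            order = None if rng is None else rng.permutation(arr.n)
            out.append(arr.rmap_vector(order)[sub])
        return out

    def combined(self, vectors) -> np.ndarray:
        w = np.array([arr.weight for arr in self.arrays])
        acc = np.zeros(vectors[0].size)
        for v, wi in zip(vectors, w):
            acc += wi * v
        return acc / w.sum()


def permutation_similarity_test(
    datasets,
    split,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    rng_seed: int = 0,
    outcome_field: str = "anxiety",
    covariate_map: dict | None = None,
) -> PermutationResult:
    """Is the spatial correlation between two groups' combined circuit maps
    stronger than chance?

    ``split`` is a pair of dataset-name lists (group A, group B).  Each
    permutation shuffles (outcome, covariates) tuples within every dataset,
    rebuilds all circuit maps, recombines per group, and recomputes the
    spatial correlation.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    names_a, names_b = (list(split[0]), list(split[1]))
    by_name = {d.name: d for d in datasets}
    for nm in names_a + names_b:
        if nm not in by_name:
            raise KeyError(f"no dataset named {nm!r}")
    perm = _StudyPermuter([by_name[nm] for nm in names_a + names_b],
                          outcome_field, covariate_map)
    ia = np.arange(len(names_a))
    ib = np.arange(len(names_a), len(names_a) + len(names_b))

    def statistic(vectors):
        wa = np.array([perm.arrays[i].weight for i in ia])
        wb = np.array([perm.arrays[i].weight for i in ib])
        map_a = sum(wi * vectors[i] for wi, i in zip(wa, ia)) / wa.sum()
        map_b = sum(wi * vectors[i] for wi, i in zip(wb, ib)) / wb.sum()
        return _pearson(map_a, map_b)

    observed = statistic(perm.dataset_vectors())
    rng = np.random.default_rng(rng_seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = statistic(perm.dataset_vectors(rng))
    return PermutationResult.from_null(observed, null, rng_seed)


def mean_cross_correlation_test(
    datasets,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    rng_seed: int = 0,
    outcome_field: str = "anxiety",
    covariate_map: dict | None = None,
) -> PermutationResult:
    """Mean pairwise spatial correlation across all dataset circuit maps,
    against the same shuffle-and-rebuild null (guards against the grouping
    step driving a similarity result)."""
    datasets = list(datasets)
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    perm = _StudyPermuter(datasets, outcome_field, covariate_map)
    pairs = list(itertools.combinations(range(len(datasets)), 2))

    def statistic(vectors):
        return float(np.mean([_pearson(vectors[i], vectors[j]) for i, j in pairs]))

    observed = statistic(perm.dataset_vectors())
    rng = np.random.default_rng(rng_seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = statistic(perm.dataset_vectors(rng))
    return PermutationResult.from_null(observed, null, rng_seed)


def peak_fwe_test(
    datasets,
    peak_xyz_mm=None,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    rng_seed: int = 0,
    outcome_field: str = "anxiety",
    covariate_map: dict | None = None,
) -> PermutationResult:
    """Max-statistic FWE test of a peak in the combined circuit map.

    Observed statistic: the combined-map value at the peak voxel (the
    in-mask maximum when ``peak_xyz_mm`` is None, i.e. the map's own peak).
    Null statistic per permutation: the maximum in-mask voxel value of the
    rebuilt combined map, which corrects for the whole-brain search.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    perm = _StudyPermuter(list(datasets), outcome_field, covariate_map)
    combined = perm.combined(perm.dataset_vectors())
    if peak_xyz_mm is None:
        observed = float(combined.max())
    else:
        ijk = np.rint(perm.grid.world_to_voxel(peak_xyz_mm)).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= np.asarray(perm.grid.shape)):
            raise VolumeError(f"peak {list(peak_xyz_mm)} maps outside the grid")
        if not perm.mask[tuple(ijk)]:
            raise VolumeError(f"peak {list(peak_xyz_mm)} lies outside the analysis mask")
        flat = np.ravel_multi_index(tuple(ijk), perm.grid.shape)
        pos = np.searchsorted(np.flatnonzero(perm.mask.reshape(-1)), flat)
        observed = float(combined[pos])
    rng = np.random.default_rng(rng_seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = perm.combined(perm.dataset_vectors(rng)).max()
    return PermutationResult.from_null(observed, null, rng_seed)


# ---- cluster peaks -------------------------------------------------------------

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


def cluster_peaks(volume: BrainVolume, threshold: float, k: int = 2):
    """Strongest suprathreshold clusters with value-weighted centres of gravity.

    Connected components (26-connectivity) of in-mask voxels strictly above
    ``threshold`` are ranked by their maximum voxel value; the top ``k``
    (fewer if fewer exist) are returned as
    ``(center_of_gravity_mm, peak_value, cluster_size)`` tuples.
    """
    supra = volume.brain_mask & (volume.data > threshold)
    if not supra.any():
        raise VolumeError(f"no in-mask voxel exceeds threshold {threshold}")
    labels, n_clusters = ndimage.label(supra, structure=_STRUCTURE_26)
    results = []
    for lab in range(1, n_clusters + 1):
        sel = labels == lab
        vals = volume.data[sel]
        coords = np.argwhere(sel).astype(float)
        weights = vals - threshold if threshold < 0 else vals
        if weights.sum() <= 0:
            cog_vox = coords.mean(axis=0)
        else:
            cog_vox = (coords * weights[:, None]).sum(axis=0) / weights.sum()
        cog_mm = volume.grid.voxel_to_world(cog_vox)
        results.append((cog_mm, float(vals.max()), int(sel.sum())))
    results.sort(key=lambda t: t[1], reverse=True)
    return results[:k]
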