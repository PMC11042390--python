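"""Seed-based functional connectivity against a (normative) connectome.

A connectome is a set of resting-state subjects, each contributing one
time-series per in-mask voxel.  Seed connectivity of a stimulation site is
computed per subject as the Pearson correlation between the site's
weight-averaged seed timecourse and every in-mask voxel, Fisher
z-transformed (atanh, with r clipped at 1 - 1e-7 to keep z finite), then
averaged across subjects.  Averaging z rather than r is the standard
variance-stabilised choice.

Also provided: the within-circuit connectivity score used to ask whether a
subject's own connectivity inside a circuit (independent of where they were
stimulated) relates to outcome, and the analogous within/between scores for
a parcellation of control networks.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .stimulation import SiteKind, StimulationSite
from .volumes import BrainGrid, BrainVolume, GridMismatchError, VolumeError

__all__ = [
    "R_CLIP",
    "ConnectivityMap",
    "ConnectomeDataset",
    "control_network_scores",
    "seed_connectivity",
    "seed_timecourse",
    "within_circuit_connectivity",
]

#: correlations are clipped to +/- (1 - R_CLIP) before atanh
R_CLIP = 1e-7

_MIN_TIMEPOINTS = 8


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with clipping so perfect correlations stay finite."""
    return np.arctanh(np.clip(r, -1.0 + R_CLIP, 1.0 - R_CLIP))


@dataclasses.dataclass
class ConnectomeDataset:
    """Multi-subject voxel time-series on one grid.

    ``subjects[s]`` is an array of shape ``(T_s, n_mask_voxels)`` whose
    columns follow ``np.flatnonzero(brain_mask)`` in C order.
    """

    grid: BrainGrid
    brain_mask: np.ndarray
    subjects: list

    def __post_init__(self) -> None:
        mask = np.asarray(self.brain_mask).astype(bool)
        if mask.shape != tuple(self.grid.shape):
            raise VolumeError("connectome mask shape does not match grid")
        if not mask.any():
            raise VolumeError("connectome brain mask is empty")
        self.brain_mask = mask
        n_vox = int(mask.sum())
        subjects = []
        for s, ts in enumerate(self.subjects):
            ts = np.asarray(ts, dtype=float)
            if ts.ndim != 2 or ts.shape[1] != n_vox:
                raise VolumeError(
                    f"subject {s}: time-series must have shape (T, {n_vox}), got {ts.shape}"
                )
            if ts.shape[0] < _MIN_TIMEPOINTS:
                raise VolumeError(f"subject {s}: need >= {_MIN_TIMEPOINTS} timepoints")
            if not np.isfinite(ts).all():
                raise VolumeError(f"subject {s}: non-finite values in time-series")
            subjects.append(ts)
        if not subjects:
            raise VolumeError("connectome needs at least one subject")
        self.subjects = subjects

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_voxels(self) -> int:
        return int(self.brain_mask.sum())

    def to_volume(self, masked_values: np.ndarray) -> BrainVolume:
        """Embed a flat in-mask vector back into a full volume (0 elsewhere)."""
        data = np.zeros(self.grid.shape, dtype=float)
        data[self.brain_mask] = masked_values
        return BrainVolume(grid=self.grid, data=data, brain_mask=self.brain_mask)


@dataclasses.dataclass
class ConnectivityMap:
    """Whole-brain Fisher-z connectivity of one stimulation site."""

    zmap: BrainVolume
    site: StimulationSite | None
    n_subjects_used: int

    def __post_init__(self) -> None:
        if self.n_subjects_used < 1:
            raise VolumeError("connectivity map must use at least one subject")
        if not np.isfinite(self.zmap.masked_values()).all():
            raise VolumeError("connectivity map has non-finite in-mask values")


def _site_mask_weights(site: StimulationSite, connectome: ConnectomeDataset) -> np.ndarray:
    """Site weights restricted to the connectome's in-mask voxel columns."""
    if site.grid != connectome.grid:
        raise GridMismatchError("site grid does not match connectome grid")
    w = site.weights.data[connectome.brain_mask]
    w = np.where(np.isfinite(w), w, 0.0)
    if w.sum() <= 0:
        raise VolumeError("stimulation site lies entirely outside the brain mask")
    return w / w.sum()


def seed_timecourse(site: StimulationSite, connectome: ConnectomeDataset, subject: int) -> np.ndarray:
    """Weight-weighted mean time-series of the site over in-mask voxels."""
    w = _site_mask_weights(site, connectome)
    ts = connectome.subjects[subject]
    return ts @ w


def _standardize_columns(a: np.ndarray):
    mu = a.mean(axis=0, keepdims=True)
    centered = a - mu
    sd = centered.std(axis=0, keepdims=True)
    ok = sd[0] > 0
    safe = np.where(sd > 0, sd, 1.0)
    return centered / safe, ok


def seed_connectivity(site: StimulationSite, connectome: ConnectomeDataset) -> ConnectivityMap:
    """Mean Fisher-z seed map of a site across all connectome subjects.

    Bilateral DBS pairs are rejected: two disjoint fields cannot be merged
    into a single seed without discarding information, so DBS sites are
    scored by circuit overlap instead (see :mod:`circuitmap.prediction`).
    """
    if site.kind is SiteKind.DBS_PAIR:
        raise ValueError(
            "seed_connectivity is undefined for bilateral DBS pairs; "
            "use dbs_overlap_score instead"
        )
    w = _site_mask_weights(site, connectome)
    z_sum = np.zeros(connectome.n_voxels)
    used = 0
    for s, ts in enumerate(connectome.subjects):
        seed = ts @ w
        sd = seed.std()
        if sd == 0:
            warnings.warn(f"subject {s}: zero-variance seed timecourse, skipped")
            continue
        seed_std = (seed - seed.mean()) / sd
        vox_std, _ = _standardize_columns(ts)
        r = (seed_std @ vox_std) / ts.shape[0]
        z_sum += fisher_z(r)
        used += 1
    if used == 0:
        raise VolumeError("all subjects had zero-variance seed timecourses")
    zmap = connectome.to_volume(z_sum / used)
    return ConnectivityMap(zmap=zmap, site=site, n_subjects_used=used)


def bulk_seed_zmaps(
    weight_rows: np.ndarray,
    connectome: ConnectomeDataset,
    subjects: list | None = None,
) -> np.ndarray:
    """Mean Fisher-z seed maps for many sites at once.

    ``weight_rows`` is ``(n_sites, n_mask_voxels)`` of non-negative seed
    weights (rows need not be normalised).  Returns ``(n_sites,
    n_mask_voxels)`` of subject-averaged Fisher z.  Used by the cohort
    pipeline where per-site calls would dominate runtime.
    """
    W = np.asarray(weight_rows, dtype=float)
    sums = W.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise VolumeError("every site must have positive in-mask weight")
    W = W / sums
    if subjects is None:
        subjects = list(range(connectome.n_subjects))
    z_sum = np.zeros((W.shape[0], connectome.n_voxels))
    counts = np.zeros(W.shape[0])
    for s in subjects:
        ts = connectome.subjects[s]
        seeds = ts @ W.T  # (T, n_sites)
        seeds_std, seed_ok = _standardize_columns(seeds)
        vox_std, _ = _standardize_columns(ts)
        r = (seeds_std.T @ vox_std) / ts.shape[0]
        z = fisher_z(r)
        z[~seed_ok] = 0.0
        z_sum += z
        counts += seed_ok
    if np.any(counts == 0):
        raise VolumeError("a site had zero-variance seeds in every subject")
    return z_sum / counts[:, None]


# ---- within-circuit and control-network connectivity ---------------------------


def _pole_indices(values: np.ndarray, top_fraction: float):
    pos = np.flatnonzero(values > 0)
    neg = np.flatnonzero(values < 0)
    if pos.size == 0 or neg.size == 0:
        raise VolumeError("circuit must have both positive and negative in-mask voxels")
    n_pos = max(int(np.ceil(top_fraction * pos.size)), 1)
    n_neg = max(int(np.ceil(top_fraction * neg.size)), 1)
    top_pos = pos[np.argsort(values[pos])[::-1][:n_pos]]
    top_neg = neg[np.argsort(values[neg])[:n_neg]]
    if top_pos.size < 2 or top_neg.size < 2:
        raise VolumeError("fewer than 2 voxels in a circuit pole")
    return top_pos, top_neg


def _subsample(idx: np.ndarray, cap: int, rng: np.random.Generator) -> np.ndarray:
    if idx.size <= cap:
        return idx
    return rng.choice(idx, size=cap, replace=False)


def _mean_pairwise_z(a: np.ndarray, b: np.ndarray | None = None) -> float:
    """Mean Fisher z over voxel pairs; within one set (i<j) if b is None."""
    a_std, a_ok = _standardize_columns(a)
    t = a.shape[0]
    if b is None:
        r = (a_std.T @ a_std) / t
        z = fisher_z(r)
        iu = np.triu_indices(z.shape[0], k=1)
        keep = a_ok[iu[0]] & a_ok[iu[1]]
        return float(z[iu][keep].mean())
    b_std, b_ok = _standardize_columns(b)
    r = (a_std.T @ b_std) / t
    z = fisher_z(r)
    keep = np.outer(a_ok, b_ok)
    return float(z[keep].mean())


def within_circuit_connectivity(
    circuit: BrainVolume,
    connectome: ConnectomeDataset,
    subject: int,
    top_fraction: float = 0.10,
    max_voxels_per_pole: int = 500,
    rng_seed: int = 0,
) -> float:
    """Connectivity within a signed circuit for one subject.

    Takes the top ``top_fraction`` of positive voxels (pole P) and of
    most-negative voxels (pole N), then returns

        mean z within P  +  mean z within N  -  mean z between P and N.

    Large poles are uniformly subsampled to at most ``max_voxels_per_pole``
    voxels (seeded) to bound the pairwise cost deterministically.  The score
    is symmetric under negating the circuit (P and N swap).
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    if circuit.grid != connectome.grid:
        raise GridMismatchError("circuit grid does not match connectome grid")
    mask = connectome.brain_mask & circuit.brain_mask
    vals = np.where(mask, circuit.data, 0.0)[connectome.brain_mask]
    top_pos, top_neg = _pole_indices(vals, top_fraction)
    rng = np.random.default_rng(rng_seed)
    top_pos = _subsample(top_pos, max_voxels_per_pole, rng)
    top_neg = _subsample(top_neg, max_voxels_per_pole, rng)
    ts = connectome.subjects[subject]
    within_p = _mean_pairwise_z(ts[:, top_pos])
    within_n = _mean_pairwise_z(ts[:, top_neg])
    between = _mean_pairwise_z(ts[:, top_pos], ts[:, top_neg])
    return within_p + within_n - between


def control_network_scores(
    connectome: ConnectomeDataset,
    subject: int,
    network_labels: BrainVolume,
    max_voxels_per_network: int = 500,
    rng_seed: int = 0,
) -> dict:
    """Within- and between-network mean pairwise Fisher z for a parcellation.

    ``network_labels`` assigns a positive integer network id per voxel
    (0 = unlabelled).  Returns ``{(i, j): score}`` for every unordered pair
    of network ids including self-pairs — 28 scores for a 7-network atlas.
    """
    if network_labels.grid != connectome.grid:
        raise GridMismatchError("label grid does not match connectome grid")
    labels = np.rint(np.where(network_labels.brain_mask, network_labels.data, 0.0)).astype(int)
    labels_m = labels[connectome.brain_mask]
    ids = sorted(int(i) for i in np.unique(labels_m) if i > 0)
    if len(ids) < 2:
        raise VolumeError("need at least 2 labelled networks")
    rng = np.random.default_rng(rng_seed)
    members = {}
    for i in ids:
        idx = np.flatnonzero(labels_m == i)
        if idx.size < 2:
            raise VolumeError(f"network {i} has fewer than 2 in-mask voxels")
        members[i] = _subsample(idx, max_voxels_per_network, rng)
    ts = connectome.subjects[subject]
    scores = {}
    for a_pos, i in enumerate(ids):
        for j in ids[a_pos:]:
            if i == j:
                scores[(i, j)] = _mean_pairwise_z(ts[:, members[i]])
            else:
                scores[(i, j)] = _mean_pairwise_z(ts[:, members[i]], ts[:, members[j]])
    return scores
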