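"""Synthetic study generator: planted circuit, connectome, and cohorts.

Everything the pipeline consumes can be generated here so that every stage
is testable end-to-end without clinical data.  The generative model mirrors
the causal structure the analysis assumes:

* a *planted circuit* — a signed sum of Gaussian bumps, the ground truth
  the pipeline should recover;
* a multi-subject *connectome* whose voxel time-series are spatially
  smoothed white noise plus a shared latent component loaded on the
  circuit (positive and negative poles anticorrelated), so that seed maps
  of circuit-adjacent sites resemble the circuit;
* patient *cohorts* (lesion blobs, cortical-shell TMS sites, or mirrored
  bilateral DBS fields placed at random) whose anxiety outcome is driven
  by the site's *noiseless* circuit engagement — computed from the model
  covariance, not from a finite-sample seed map, so recovery targets
  measure estimation, not generation — plus an additive latent-depression
  confound calibrated to a target anxiety-depression correlation and
  independent Gaussian noise.

Site placement is random with respect to outcome (the as-if-random
assumption of lesion network mapping), and every draw is a pure function
of the spec's seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter

from .connectivity import ConnectomeDataset, ConnectivityMap, bulk_seed_zmaps, fisher_z
from .mapping import CohortDataset, Modality, PatientRecord
from .stimulation import (
    DEFAULT_TMS_RADIUS_MM,
    SiteKind,
    StimulationSite,
    dbs_pair_site,
    lesion_site,
    tms_site,
)
from .volumes import BrainGrid, BrainVolume, VolumeError, make_grid

__all__ = [
    "SyntheticSpec",
    "attach_connectivity",
    "make_brain_mask",
    "make_circuit",
    "make_cohort",
    "make_connectome",
    "make_study",
]

#: pooled anxiety-depression correlation the confound is calibrated to
DEFAULT_CONFOUND_RHO = 0.53


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of one synthetic study component.

    ``effect_beta`` scales the site-to-anxiety causal effect; at 0 the
    outcome is pure confound plus noise (the null).  ``confound_rho`` is
    the *target* correlation between recorded anxiety and depression; the
    depression coefficient is solved analytically so the population
    correlation equals the target.  ``smoothness_mm`` is the Gaussian
    kernel sigma of the spatial autocorrelation of the connectome noise.
    """

    grid_shape: tuple = (16, 16, 16)
    voxel_size_mm: float = 2.0
    n_subjects: int = 10
    n_timepoints: int = 120
    smoothness_mm: float = 3.0
    circuit_peaks: tuple = (
        ((6.0, 6.0, 6.0), 1.0, 5.0),
        ((-6.0, -6.0, -6.0), -1.0, 5.0),
    )
    latent_strength: float = 1.0
    effect_beta: float = 0.5
    confound_rho: float = DEFAULT_CONFOUND_RHO
    noise_sigma: float = 1.0
    n_patients: int = 100
    modality: Modality = Modality.LESION
    rng_seed: int = 0
    mask_radius_frac: float = 0.9

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        if self.n_timepoints < 32:
            raise ValueError("need n_timepoints >= 32")
        if self.n_subjects < 1:
            raise ValueError("need n_subjects >= 1")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if not abs(self.confound_rho) < 1:
            raise ValueError("|confound_rho| must be < 1")
        if not self.circuit_peaks:
            raise ValueError("need at least one circuit peak")

    @property
    def grid(self) -> BrainGrid:
        return make_grid(self.grid_shape, self.voxel_size_mm, centered=True)

    @property
    def sigma_vox(self) -> np.ndarray:
        return np.asarray(self.smoothness_mm, dtype=float) / self.grid.voxel_size_mm

    def replace(self, **kwargs) -> "SyntheticSpec":
        return dataclasses.replace(self, **kwargs)


# ---- geometry ------------------------------------------------------------------


def make_brain_mask(spec: SyntheticSpec) -> np.ndarray:
    """Spherical analysis mask: radius = mask_radius_frac x half-extent."""
    grid = spec.grid
    coords = grid.voxel_centers_mm()
    half_extent = (np.asarray(grid.shape) * grid.voxel_size_mm).min() / 2.0
    radius = spec.mask_radius_frac * half_extent
    return np.linalg.norm(coords, axis=-1) <= radius


def _radial_mm(grid: BrainGrid) -> np.ndarray:
    return np.linalg.norm(grid.voxel_centers_mm(), axis=-1)


def make_circuit(spec: SyntheticSpec) -> BrainVolume:
    """Planted ground-truth circuit: signed Gaussian bumps, max |value| = 1."""
    grid = spec.grid
    mask = make_brain_mask(spec)
    coords = grid.voxel_centers_mm()
    data = np.zeros(grid.shape)
    for center_mm, sign, width_mm in spec.circuit_peaks:
        center = np.asarray(center_mm, dtype=float)
        if not grid.contains_world(center):
            raise VolumeError(f"circuit peak {center.tolist()} lies outside the grid")
        d2 = ((coords - center) ** 2).sum(axis=-1)
        data += float(sign) * np.exp(-0.5 * d2 / float(width_mm) ** 2)
    peak = np.abs(data[mask]).max()
    if peak == 0:
        raise VolumeError("circuit is identically zero inside the mask")
    data = np.where(mask, data / peak, 0.0)
    return BrainVolume(grid=grid, data=data, brain_mask=mask)


# ---- connectome ----------------------------------------------------------------


def _double_filter(vol: np.ndarray, sigma_vox: np.ndarray) -> np.ndarray:
    """Apply the smoothing operator and its transpose (G G^T v)."""
    if np.all(sigma_vox == 0):
        return vol
    once = gaussian_filter(vol, sigma=tuple(sigma_vox), mode="constant")
    return gaussian_filter(once, sigma=tuple(sigma_vox), mode="constant")


def _kernel_norm(spec: SyntheticSpec) -> float:
    """Per-voxel variance of unit white noise after smoothing, (G G^T)_vv
    at an interior voxel (edge voxels differ slightly; the spherical mask
    keeps the analysis away from the worst corners)."""
    if np.all(spec.sigma_vox == 0):
        return 1.0
    impulse = np.zeros(spec.grid.shape)
    center = tuple(s // 2 for s in spec.grid.shape)
    impulse[center] = 1.0
    return float(_double_filter(impulse, spec.sigma_vox)[center])


def make_connectome(spec: SyntheticSpec) -> ConnectomeDataset:
    """Multi-subject synthetic resting-state connectome.

    Per subject: time-series = smoothed white noise (rescaled to unit voxel
    variance) plus ``latent_strength * circuit_value * u(t)`` with a shared
    standard-normal latent ``u``, so voxels in the positive and negative
    circuit poles are mutually anticorrelated.
    """
    grid = spec.grid
    mask = make_brain_mask(spec)
    circuit = make_circuit(spec)
    lam = circuit.data
    nu = _kernel_norm(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 101]))
    sigma = spec.sigma_vox
    subjects = []
    for _ in range(spec.n_subjects):
        noise = rng.standard_normal((spec.n_timepoints, *grid.shape))
        if np.any(sigma > 0):
            noise = gaussian_filter(noise, sigma=(0.0, *sigma), mode="constant")
            noise /= np.sqrt(nu)
        u = rng.standard_normal(spec.n_timepoints)
        ts = noise + spec.latent_strength * u[:, None, None, None] * lam[None]
        subjects.append(ts[:, mask])
    return ConnectomeDataset(grid=grid, brain_mask=mask, subjects=subjects)


# ---- noiseless fingerprints ----------------------------------------------------


def circuit_fingerprint(site: StimulationSite, spec: SyntheticSpec,
                        circuit: BrainVolume) -> np.ndarray:
    """Model-implied (noiseless) seed Fisher-z map of a site, on the mask.

    Derived from the generative covariance: the seed is the weight-averaged
    time-series, whose covariance with a voxel splits into the latent part
    ``g^2 lambda_s lambda_v`` and the smoothing-kernel part ``(G G^T w)_v``.
    """
    mask = circuit.brain_mask
    lam = circuit.data
    w = np.where(mask, site.weights.data, 0.0)
    s_tot = w.sum()
    if s_tot <= 0:
        raise VolumeError("site has no in-mask weight")
    w_norm = w / s_tot
    g = spec.latent_strength
    nu = _kernel_norm(spec)
    lam_s = float((w_norm * lam).sum())
    kw = _double_filter(w_norm, spec.sigma_vox) / nu
    cov_sv = g * g * lam_s * lam + kw
    var_s = g * g * lam_s * lam_s + float((w_norm * kw).sum())
    var_v = g * g * lam * lam + 1.0
    with np.errstate(invalid="ignore"):
        r = cov_sv / np.sqrt(var_s * var_v)
    return fisher_z(r[mask])


def _true_score(site: StimulationSite, spec: SyntheticSpec,
                circuit: BrainVolume) -> float:
    """Noiseless circuit engagement of one site: fingerprint-circuit spatial
    correlation for seeds, hemifield-summed mean circuit value for DBS."""
    if site.kind is SiteKind.DBS_PAIR:
        score = 0.0
        for field in (site.weights, site.weights_right):
            sel = (field.data > 0) & circuit.brain_mask
            if sel.any():
                score += float(circuit.data[sel].mean())
        return score
    fp = circuit_fingerprint(site, spec, circuit)
    truth = circuit.masked_values()
    fp_c = fp - fp.mean()
    t_c = truth - truth.mean()
    return float(fp_c @ t_c / (np.linalg.norm(fp_c) * np.linalg.norm(t_c)))


# ---- site placement ------------------------------------------------------------


def _random_lesion(grid, mask, rng) -> StimulationSite:
    idx = np.argwhere(mask)
    center = idx[rng.integers(idx.shape[0])]
    size = int(rng.integers(3, 11))  # blob of 3-10 voxels
    d2 = ((idx - center) ** 2).sum(axis=1)
    chosen = idx[np.argsort(d2, kind="stable")[:size]]
    data = np.zeros(grid.shape)
    data[tuple(chosen.T)] = 1.0
    return lesion_site(BrainVolume(grid=grid, data=data, brain_mask=mask))


def _random_tms(grid, mask, spec, rng) -> StimulationSite:
    radial = _radial_mm(grid)
    half_extent = (np.asarray(grid.shape) * grid.voxel_size_mm).min() / 2.0
    r_mask = spec.mask_radius_frac * half_extent
    shell = mask & (radial >= 0.7 * r_mask)
    idx = np.argwhere(shell)
    center_vox = idx[rng.integers(idx.shape[0])]
    center_mm = grid.voxel_to_world(center_vox)
    return tms_site(grid, center_mm, DEFAULT_TMS_RADIUS_MM, brain_mask=mask)


def _sphere_mask(grid, center_mm, radius_mm) -> np.ndarray:
    coords = grid.voxel_centers_mm()
    return np.linalg.norm(coords - np.asarray(center_mm), axis=-1) <= radius_mm


def _random_dbs_pair(grid, mask, spec, rng) -> StimulationSite:
    radial = _radial_mm(grid)
    half_extent = (np.asarray(grid.shape) * grid.voxel_size_mm).min() / 2.0
    r_mask = spec.mask_radius_frac * half_extent
    coords = grid.voxel_centers_mm()
    deep = mask & (radial <= 0.5 * r_mask) & (coords[..., 0] < -0.5)
    idx = np.argwhere(deep)
    if idx.size == 0:
        raise VolumeError("mask too small to place a deep DBS electrode")
    left_mm = grid.voxel_to_world(idx[rng.integers(idx.shape[0])])
    right_mm = left_mm * np.array([-1.0, 1.0, 1.0])  # mirrored across midline
    field_radius = 1.3 * float(np.max(grid.voxel_size_mm))
    left = _sphere_mask(grid, left_mm, field_radius) & mask
    right = _sphere_mask(grid, right_mm, field_radius) & mask
    return dbs_pair_site(
        BrainVolume(grid=grid, data=left.astype(float), brain_mask=mask),
        BrainVolume(grid=grid, data=right.astype(float), brain_mask=mask),
    )


def _confound_coefficient(spec: SyntheticSpec) -> float:
    """Depression loading solving corr(anxiety, depression) = confound_rho
    when the standardized true score has unit variance."""
    rho = spec.confound_rho
    b2 = spec.effect_beta ** 2 + spec.noise_sigma ** 2
    return float(np.sign(rho) * np.sqrt(rho * rho * b2 / (1.0 - rho * rho)))


# ---- cohorts -------------------------------------------------------------------


def attach_connectivity(records, connectome: ConnectomeDataset,
                        subject_for_record=None) -> None:
    """Compute and attach seed connectivity maps in bulk.

    ``subject_for_record`` maps record index -> connectome subject for
    individualized cohorts; None averages over all subjects (normative).
    DBS records are skipped (their seed map is undefined).
    """
    seedable = [(i, rec) for i, rec in enumerate(records)
                if rec.site.kind is not SiteKind.DBS_PAIR]
    if not seedable:
        return
    mask = connectome.brain_mask
    if subject_for_record is None:
        w_rows = np.stack([
            np.where(np.isfinite(rec.site.weights.data), rec.site.weights.data, 0.0)[mask]
            for _, rec in seedable
        ])
        z = bulk_seed_zmaps(w_rows, connectome)
        n_used = connectome.n_subjects
        for (_, rec), z_row in zip(seedable, z):
            rec.conn_map = ConnectivityMap(zmap=connectome.to_volume(z_row),
                                           site=rec.site, n_subjects_used=n_used)
    else:
        by_subject: dict = {}
        for i, rec in seedable:
            by_subject.setdefault(int(subject_for_record[i]), []).append((i, rec))
        for subj, group in by_subject.items():
            w_rows = np.stack([
                np.where(np.isfinite(rec.site.weights.data), rec.site.weights.data, 0.0)[mask]
                for _, rec in group
            ])
            z = bulk_seed_zmaps(w_rows, connectome, subjects=[subj])
            for (_, rec), z_row in zip(group, z):
                rec.conn_map = ConnectivityMap(zmap=connectome.to_volume(z_row),
                                               site=rec.site, n_subjects_used=1)


def make_cohort(spec: SyntheticSpec, circuit: BrainVolume,
                connectome: ConnectomeDataset, name: str | None = None) -> CohortDataset:
    """Generate one patient cohort under the planted causal model.

    anxiety_i = effect_beta * s_i + c * d_i + eps_i, where s_i is the
    standardized noiseless circuit-engagement score of patient i's site,
    d_i ~ N(0,1) is the latent depression confound (recorded as the
    depression score), c solves the target anxiety-depression correlation,
    and eps_i ~ N(0, noise_sigma^2).
    """
    grid = spec.grid
    if circuit.grid != grid or connectome.grid != grid:
        raise VolumeError("circuit/connectome grid does not match the spec grid")
    mask = connectome.brain_mask
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 202]))
    modality = spec.modality
    sites = []
    for _ in range(spec.n_patients):
        if modality is Modality.LESION:
            sites.append(_random_lesion(grid, mask, rng))
        elif modality in (Modality.TMS_SCALP, Modality.TMS_INDIVIDUALIZED):
            sites.append(_random_tms(grid, mask, spec, rng))
        else:
            sites.append(_random_dbs_pair(grid, mask, spec, rng))

    raw = np.array([_true_score(site, spec, circuit) for site in sites])
    sd = raw.std()
    s_tilde = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)

    d = rng.standard_normal(spec.n_patients)
    eps = rng.normal(0.0, spec.noise_sigma, spec.n_patients)
    c = _confound_coefficient(spec)
    anxiety = spec.effect_beta * s_tilde + c * d + eps
    depression = d
    baseline_anx = rng.standard_normal(spec.n_patients)
    baseline_dep = rng.standard_normal(spec.n_patients)
    anx_disorder = (rng.random(spec.n_patients) < 0.5).astype(float)

    records = []
    for i, site in enumerate(sites):
        extras = {
            "true_score": float(s_tilde[i]),
            "anxiety_disorder": float(anx_disorder[i]),
        }
        if modality is not Modality.LESION:
            extras["baseline_anxiety"] = float(baseline_anx[i])
        if modality is Modality.DBS:
            extras["baseline_depression"] = float(baseline_dep[i])
        records.append(PatientRecord(
            id=f"{modality.value}-{i:04d}",
            site=site,
            anxiety=float(anxiety[i]),
            depression=float(depression[i]),
            extra_covariates=extras,
        ))

    if modality is Modality.TMS_INDIVIDUALIZED:
        subject_for_record = [i % connectome.n_subjects for i in range(len(records))]
        attach_connectivity(records, connectome, subject_for_record)
    elif modality is not Modality.DBS:
        attach_connectivity(records, connectome)

    return CohortDataset(name=name or f"synthetic-{modality.value}",
                         modality=modality, records=records)


def make_study(spec: SyntheticSpec, modalities=None, n_patients=None,
               names=None) -> tuple:
    """Generate a full multi-cohort study sharing one connectome and circuit.

    Returns ``(circuit, connectome, datasets)``.  Each cohort gets its own
    derived seed so cohorts differ while the whole study is reproducible
    from the spec seed.
    """
    if modalities is None:
        modalities = (Modality.TMS_SCALP, Modality.TMS_INDIVIDUALIZED,
                      Modality.LESION, Modality.DBS)
    modalities = [Modality(m) for m in modalities]
    circuit = make_circuit(spec)
    connectome = make_connectome(spec)
    datasets = []
    for i, modality in enumerate(modalities):
        sub = spec.replace(modality=modality,
                           rng_seed=int(spec.rng_seed * 1000 + 7 * i + 1) % (2**31),
                           n_patients=(n_patients[i] if n_patients else spec.n_patients))
        name = names[i] if names else f"{modality.value}-{i}"
        datasets.append(make_cohort(sub, circuit, connectome, name=name))
    return circuit, connectome, datasets
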