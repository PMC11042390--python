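"""Voxel-weight models of causal perturbations: lesions, TMS sites, DBS fields.

Each perturbation is represented as a weight map in [0, 1] on the analysis
grid.  Lesions and DBS fields are binary masks; a TMS site is a decaying
sphere around the scalp coordinate: weight falls off linearly with world
distance from the centre and reaches zero at the maximal radius (12 mm by
default).  DBS patients carry a bilateral pair of fields which are kept
separate — they are scored per hemifield, never merged into one seed.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np

from .volumes import BrainGrid, BrainVolume, GridMismatchError, VolumeError

__all__ = [
    "DEFAULT_TMS_RADIUS_MM",
    "SiteKind",
    "StimulationSite",
    "dbs_pair_site",
    "lesion_site",
    "tms_site",
]

#: maximal radius of the decaying TMS sphere, in millimetres
DEFAULT_TMS_RADIUS_MM = 12.0


class SiteKind(str, enum.Enum):
    LESION = "lesion"
    TMS = "tms"
    DBS_PAIR = "dbs_pair"


@dataclasses.dataclass
class StimulationSite:
    """One causal perturbation as a voxel-weight map.

    ``weights_right`` is present exactly for bilateral DBS pairs, in which
    case ``weights`` holds the left field.  ``size_voxels`` counts strictly
    positive weights and doubles as the lesion-size covariate.
    """

    kind: SiteKind
    weights: BrainVolume
    weights_right: BrainVolume | None = None
    size_voxels: int = 0

    def __post_init__(self) -> None:
        self.kind = SiteKind(self.kind)
        for vol, label in ((self.weights, "weights"), (self.weights_right, "weights_right")):
            if vol is None:
                continue
            vals = vol.data
            if np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1.0 + 1e-12:
                raise VolumeError(f"site {label} must lie in [0, 1]")
        if (self.weights_right is not None) != (self.kind is SiteKind.DBS_PAIR):
            raise VolumeError("weights_right is present iff kind is dbs_pair")
        total = np.count_nonzero(self.weights.data > 0)
        if self.weights_right is not None:
            if self.weights_right.grid != self.weights.grid:
                raise GridMismatchError("DBS hemifields must share a grid")
            total += np.count_nonzero(self.weights_right.data > 0)
        if total == 0:
            raise VolumeError("stimulation site has no positive weight")
        self.size_voxels = int(total)

    @property
    def grid(self) -> BrainGrid:
        return self.weights.grid


def tms_site(
    grid: BrainGrid,
    center_mm,
    max_radius_mm: float = DEFAULT_TMS_RADIUS_MM,
    brain_mask: np.ndarray | None = None,
) -> StimulationSite:
    """Decaying-sphere model of a TMS stimulation site.

    The weight at a voxel with world distance ``d`` from the centre is
    ``max(0, 1 - d / max_radius_mm)``: 1 at the centre, 0 at and beyond the
    maximal radius.  The linear profile is the simplest monotone decay with
    compact support; swap this function to change the profile.
    """
    if max_radius_mm <= 0:
        raise ValueError("max_radius_mm must be positive")
    center = np.asarray(center_mm, dtype=float)
    if not grid.contains_world(center):
        raise ValueError(f"TMS centre {center.tolist()} maps outside the grid")
    coords = grid.voxel_centers_mm()
    dist = np.linalg.norm(coords - center, axis=-1)
    weights = np.clip(1.0 - dist / float(max_radius_mm), 0.0, 1.0)
    vol = BrainVolume(grid=grid, data=weights, brain_mask=brain_mask)
    return StimulationSite(kind=SiteKind.TMS, weights=vol)


def _check_binary(vol: BrainVolume, label: str) -> None:
    vals = vol.data[np.isfinite(vol.data)]
    if not np.all((vals == 0) | (vals == 1)):
        raise VolumeError(f"{label} must be binary (values in {{0, 1}})")


def lesion_site(mask: BrainVolume) -> StimulationSite:
    """Binary lesion mask as a stimulation site; records lesion size in voxels."""
    _check_binary(mask, "lesion mask")
    if np.count_nonzero(mask.data > 0) == 0:
        raise VolumeError("lesion mask is empty")
    return StimulationSite(kind=SiteKind.LESION, weights=mask)


def dbs_pair_site(left_field: BrainVolume, right_field: BrainVolume) -> StimulationSite:
    """Bilateral DBS stimulation-field pair.

    Both hemifields are retained separately; a single empty hemifield is
    accepted (unilateral edge case) and contributes zero to overlap scores.
    """
    _check_binary(left_field, "left DBS field")
    _check_binary(right_field, "right DBS field")
    if left_field.grid != right_field.grid:
        raise GridMismatchError("DBS hemifields must share a grid")
    n_left = np.count_nonzero(left_field.data > 0)
    n_right = np.count_nonzero(right_field.data > 0)
    if n_left + n_right == 0:
        raise VolumeError("both DBS hemifields are empty")
    return StimulationSite(kind=SiteKind.DBS_PAIR, weights=left_field, weights_right=right_field)
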