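"""Volume data model: grids, brain volumes, NIfTI I/O, coordinate transforms.

Every stage of the pipeline operates on scalar fields sampled on a fixed
3-D voxel grid in a standard (MNI-style) millimetre space.  The grid is
defined entirely by its shape and the NIfTI affine; voxel indices are
0-based and world coordinates follow the affine exactly, with no implicit
axis flipping.  All volumes entering one analysis must share a grid —
resampling and registration are upstream concerns and a mismatch is a
hard error.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GRID_ATOL",
    "BrainGrid",
    "BrainVolume",
    "GridMismatchError",
    "VolumeError",
    "make_grid",
    "read_volume",
    "write_volume",
]

#: absolute tolerance for grid (affine) equality
GRID_ATOL = 1e-6


class VolumeError(ValueError):
    """Invalid volume data or metadata."""


class GridMismatchError(VolumeError):
    """Two volumes that must share a grid do not."""


@dataclasses.dataclass(frozen=True)
class BrainGrid:
    """A 3-D voxel grid with its voxel-to-world affine.

    Parameters
    ----------
    shape:
        Number of voxels along each axis.
    affine:
        4x4 matrix mapping homogeneous 0-based voxel indices to world
        millimetres (the NIfTI convention).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise VolumeError(f"grid shape must be a positive integer triple, got {self.shape!r}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise VolumeError(f"affine must be 4x4, got shape {affine.shape}")
        if not np.allclose(affine[3], [0.0, 0.0, 0.0, 1.0]):
            raise VolumeError("affine bottom row must be [0, 0, 0, 1]")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise VolumeError("affine is not invertible")
        affine = affine.copy()
        affine.flags.writeable = False
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Physical voxel edge lengths (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BrainGrid):
            return NotImplemented
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=GRID_ATOL, rtol=0.0
        )

    def __hash__(self) -> int:  # affine is compared approximately; hash on shape only
        return hash(self.shape)

    # ---- coordinate transforms -------------------------------------------------

    def voxel_to_world(self, ijk) -> np.ndarray:
        """Map (continuous) voxel indices to world millimetres."""
        ijk = np.asarray(ijk, dtype=float)
        return nib.affines.apply_affine(self.affine, ijk)

    def world_to_voxel(self, xyz_mm) -> np.ndarray:
        """Map world millimetres to continuous 0-based voxel coordinates."""
        xyz = np.asarray(xyz_mm, dtype=float)
        return nib.affines.apply_affine(np.linalg.inv(self.affine), xyz)

    def contains_world(self, xyz_mm) -> bool:
        """True if the point maps strictly inside the voxel lattice bounds."""
        ijk = self.world_to_voxel(xyz_mm)
        lo = -0.5
        hi = np.asarray(self.shape, dtype=float) - 0.5
        return bool(np.all(ijk > lo) and np.all(ijk < hi))

    def voxel_centers_mm(self) -> np.ndarray:
        """World coordinates of all voxel centres, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_to_world(idx).reshape(*self.shape, 3)


def make_grid(shape=(16, 16, 16), voxel_size_mm=2.0, centered: bool = True) -> BrainGrid:
    """Convenience constructor: axis-aligned grid, optionally centred on 0 mm."""
    shape = tuple(int(s) for s in shape)
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vs
    if centered:
        affine[:3, 3] = -vs * (np.asarray(shape) - 1) / 2.0
    return BrainGrid(shape=shape, affine=affine)


@dataclasses.dataclass
class BrainVolume:
    """A scalar field on a :class:`BrainGrid` with an analysis mask.

    ``brain_mask`` marks the voxels eligible for analysis; non-finite data
    values are forced outside the mask at construction so NaN/inf can never
    propagate into correlations downstream.
    """

    grid: BrainGrid
    data: np.ndarray
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.shape != tuple(self.grid.shape):
            raise VolumeError(
                f"data shape {data.shape} does not match grid shape {self.grid.shape}"
            )
        if self.brain_mask is None:
            mask = np.ones(self.grid.shape, dtype=bool)
        else:
            mask = np.asarray(self.brain_mask).astype(bool)
            if mask.shape != tuple(self.grid.shape):
                raise VolumeError(
                    f"mask shape {mask.shape} does not match grid shape {self.grid.shape}"
                )
        mask = mask & np.isfinite(data)
        if not mask.any():
            raise VolumeError("brain mask is empty (no finite in-mask voxel)")
        self.data = data
        self.brain_mask = mask

    # ---- helpers ---------------------------------------------------------------

    def masked_values(self) -> np.ndarray:
        """Flat vector of in-mask data values."""
        return self.data[self.brain_mask]

    def with_data(self, data, brain_mask=None) -> "BrainVolume":
        """New volume on the same grid (mask defaults to this volume's mask)."""
        return BrainVolume(
            grid=self.grid,
            data=data,
            brain_mask=self.brain_mask if brain_mask is None else brain_mask,
        )

    def same_grid(self, other: "BrainVolume | BrainGrid") -> bool:
        grid = other.grid if isinstance(other, BrainVolume) else other
        return self.grid == grid


def _require_grid(grid: BrainGrid, expected: BrainGrid | None, context: str) -> None:
    if expected is not None and grid != expected:
        raise GridMismatchError(
            f"{context}: grid shape={grid.shape} does not match expected "
            f"shape={expected.shape} (affines must also agree within {GRID_ATOL})"
        )


def read_volume(
    path,
    expected_grid: BrainGrid | None = None,
    brain_mask: np.ndarray | None = None,
) -> BrainVolume:
    """Read a 3-D NIfTI-1 volume.

    The grid comes from the file header.  If ``expected_grid`` is given and
    does not match, a :class:`GridMismatchError` is raised — the caller must
    resample upstream; this package never resamples silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    grid = BrainGrid(shape=data.shape, affine=np.asarray(img.affine))
    _require_grid(grid, expected_grid, str(path))
    return BrainVolume(grid=grid, data=data, brain_mask=brain_mask)


def write_volume(volume: BrainVolume, path) -> Path:
    """Write a volume as NIfTI-1.  Data are stored as float64, affine verbatim."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.data.astype(np.float64), np.asarray(volume.grid.affine))
    nib.save(img, str(path))
    return path


def world_to_voxel(grid: BrainGrid, xyz_mm) -> np.ndarray:
    """Functional alias for :meth:`BrainGrid.world_to_voxel`."""
    return grid.world_to_voxel(xyz_mm)


def voxel_to_world(grid: BrainGrid, ijk) -> np.ndarray:
    """Functional alias for :meth:`BrainGrid.voxel_to_world`."""
    return grid.voxel_to_world(ijk)
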