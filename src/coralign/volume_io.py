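"""NIfTI volume I/O, isotropic resampling, and the multiresolution pyramid.

The in-memory containers (:class:`Volume`, :class:`LabelVolume`) carry only
what the registration pipeline consumes: a 3-D grid, its voxel spacing in mm
and the world position of voxel (0,0,0).  Voxel centers live at
``index * spacing + origin``; all interpolation happens in this frame.
Orientation matrices beyond spacing/origin are preserved on write when a file
was the source, but are never used in computation.

The pyramid follows the classic 8/4/2/1 mm multiresolution scheme: the input
is first resampled to an isotropic 1 mm grid, then repeatedly 2x2x2
block-averaged (edge blocks truncated) to obtain the 2, 4 and 8 mm levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "LabelVolume",
    "Pyramid",
    "read_volume",
    "read_labels",
    "write_volume",
    "write_labels",
    "resample_isotropic",
    "build_pyramid",
]

PYRAMID_LEVELS_MM = (8, 4, 2, 1)


class VolumeError(ValueError):
    """Raised on invalid volumes or I/O failures."""


@dataclass
class Volume:
    """A 3-D scalar image on a regular anisotropic grid.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Finite floating-point intensities.
    spacing : ndarray, shape (3,)
        Voxel side lengths in mm, all positive.
    origin : ndarray, shape (3,)
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    affine: np.ndarray | None = None  # source NIfTI affine, if file-backed
    _world: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.data.ndim != 3:
            raise VolumeError(f"expected a 3-D grid, got ndim={self.data.ndim}")
        if any(d < 1 for d in self.data.shape):
            raise VolumeError(f"degenerate dimensions {self.data.shape}")
        if np.any(self.spacing <= 0):
            raise VolumeError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.data.shape))

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical extent per axis: dims * spacing."""
        return np.asarray(self.data.shape) * self.spacing

    @property
    def center_world(self) -> np.ndarray:
        """World coordinate of the grid's geometric center."""
        return self.origin + (np.asarray(self.data.shape) - 1) / 2.0 * self.spacing

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (3, n_voxels).

        Cached: registration evaluates thousands of candidate transforms
        against the same grid, so this is computed once per volume.
        """
        if self._world is None or self._world.shape[1] != self.n_voxels:
            idx = np.indices(self.data.shape, dtype=np.float64).reshape(3, -1)
            self._world = idx * self.spacing[:, None] + self.origin[:, None]
        return self._world

    def world_to_index(self, points_world: np.ndarray) -> np.ndarray:
        """Map world-coordinate points (3, N) to fractional voxel indices."""
        return (points_world - self.origin[:, None]) / self.spacing[:, None]


@dataclass
class LabelVolume:
    """A 3-D grid of non-negative integer labels; 0 is background."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise VolumeError(f"expected a 3-D label grid, got ndim={data.ndim}")
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded):
                raise VolumeError("label volume holds non-integer values")
            data = rounded.astype(np.int32)
        if data.min() < 0:
            raise VolumeError("labels must be non-negative")
        self.data = data.astype(np.int32, copy=False)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels(self) -> np.ndarray:
        """Sorted foreground label values present in the volume."""
        u = np.unique(self.data)
        return u[u > 0]


@dataclass
class Pyramid:
    """Multiresolution stack, coarsest (8 mm) first."""

    levels: list[Volume]
    spacings_mm: tuple[int, ...] = PYRAMID_LEVELS_MM

    def level(self, mm: int) -> Volume:
        return self.levels[self.spacings_mm.index(mm)]


def _load(path):
    img = nib.load(str(path))
    if img.ndim != 3:
        raise VolumeError(f"{path}: expected a 3-D image, got shape {img.shape}")
    data = np.asanyarray(img.dataobj)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
    affine = np.asarray(img.affine, dtype=np.float64)
    origin = affine[:3, 3].copy()
    return data, spacing, origin, affine


def read_volume(path) -> Volume:
    """Load a 3-D scalar NIfTI-1 image.

    Raises :class:`VolumeError` for missing files, 4-D/non-scalar images, or
    non-finite voxels (the error names the affected voxel count).
    """
    data, spacing, origin, affine = _load(path)
    data = data.astype(np.float64)
    bad = int(np.count_nonzero(~np.isfinite(data)))
    if bad:
        raise VolumeError(f"{path}: {bad} non-finite voxel(s)")
    return Volume(data, spacing, origin, affine=affine)


def read_labels(path) -> LabelVolume:
    """Load a 3-D integer label NIfTI-1 image (0 = background)."""
    data, spacing, origin, affine = _load(path)
    return LabelVolume(data, spacing, origin, affine=affine)


def _affine_for(vol) -> np.ndarray:
    if vol.affine is not None:
        return vol.affine
    aff = np.diag(np.append(vol.spacing, 1.0))
    aff[:3, 3] = vol.origin
    return aff


def write_volume(volume: Volume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float64), _affine_for(volume))
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))


def write_labels(labels: LabelVolume, path) -> None:
    img = nib.Nifti1Image(labels.data.astype(np.int32), _affine_for(labels))
    img.header.set_zooms(tuple(labels.spacing))
    nib.save(img, str(path))


def resample_isotropic(volume: Volume, target_mm: float) -> Volume:
    """Trilinearly resample onto an isotropic ``target_mm`` grid.

    Output dimensions are ``ceil(extent / target_mm)`` per axis; samples
    falling outside the source extent take the nearest edge value.  Axes with
    a single slice cannot be interpolated and are rejected.
    """
    if target_mm <= 0:
        raise VolumeError("target_mm must be positive")
    if any(d < 2 for d in volume.shape):
        raise VolumeError(f"cannot resample degenerate axes {volume.shape}")
    out_dims = tuple(
        int(math.ceil(e / target_mm)) for e in volume.extent_mm
    )
    idx = np.indices(out_dims, dtype=np.float64).reshape(3, -1)
    # output voxel centers share the input origin
    src_index = idx * (target_mm / volume.spacing[:, None])
    vals = ndimage.map_coordinates(
        volume.data, src_index, order=1, mode="nearest"
    )
    return Volume(
        vals.reshape(out_dims),
        spacing=np.full(3, float(target_mm)),
        origin=volume.origin.copy(),
    )


def _block_mean(data: np.ndarray, factor: int = 2) -> np.ndarray:
    """Block-average by ``factor`` along every axis; edge blocks truncated."""
    out = data
    for ax in range(3):
        n = out.shape[ax]
        starts = np.arange(0, n, factor)
        sums = np.add.reduceat(out, starts, axis=ax)
        sizes = np.diff(np.append(starts, n)).astype(np.float64)
        shape = [1, 1, 1]
        shape[ax] = len(starts)
        out = sums / sizes.reshape(shape)
    return out


def build_pyramid(volume: Volume) -> Pyramid:
    """Build the 8/4/2/1 mm pyramid from a 1 mm isotropic volume.

    Each coarser level is the 2x2x2 block mean of the next finer one, so
    level dimensions follow the ceiling-halving recurrence and the global
    mean is conserved exactly when all dimensions divide evenly.
    """
    if not np.allclose(volume.spacing, 1.0, atol=1e-6):
        raise VolumeError(
            f"pyramid input must be 1 mm isotropic, got spacing {volume.spacing}"
        )
    levels = [volume]
    for _ in range(3):
        prev = levels[-1]
        data = _block_mean(prev.data, 2)
        # a 2x2x2 block of fine voxels is centered half a fine voxel beyond
        # the first voxel's center
        origin = prev.origin + 0.5 * prev.spacing
        levels.append(Volume(data, spacing=prev.spacing * 2, origin=origin))
    return Pyramid(levels=levels[::-1])
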