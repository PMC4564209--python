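"""Deterministic T1-like phantoms with known ground-truth transforms.

A phantom is a stack of nested ellipsoids with distinct mean intensities —
an outer "scalp/skull" shell, a "cortex"-like body and a dark
"ventricle"-like core — with optional additive Gaussian noise and a smooth
multiplicative bias field.  Semi-axes differ per axis and the core is
off-center, so the phantom has no rotational symmetry and both rotations
and translations are identifiable.  A light Gaussian blur (default 1 voxel)
on the intensity image emulates partial-volume averaging at tissue borders;
voxels deep inside a structure keep their exact specified mean.

Companions generate a moved copy under a known affine (resampled through
the inverse map, so registering moved onto original recovers the stated
parameters) or under a known smooth random deformation (Gaussian-filtered
white noise rescaled to a target amplitude).  Everything is seeded and
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .affine_register import AffineTransform
from .symmetric_cc_register import DisplacementField
from .volume_io import LabelVolume, Volume

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "apply_known_affine",
    "apply_known_deformation",
]

# ellipsoid semi-axes as fractions of the half-extent per axis, outer first;
# distinct per axis so orientation is identifiable
_SEMI_AXES = (
    (0.88, 0.76, 0.66),   # scalp/skull shell
    (0.70, 0.60, 0.52),   # cortex-like body
    (0.22, 0.18, 0.14),   # ventricle-like core
)
_CORE_OFFSET = (0.10, 0.06, -0.04)  # core center offset, fraction of half-extent


@dataclass
class PhantomSpec:
    """Generator settings; the same seed always yields the same phantom."""

    size: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    means: tuple[float, ...] = (90.0, 150.0, 45.0)   # shell, body, core
    noise_sd: float = 2.0
    bias_amplitude: float = 0.0
    bias_smoothness_mm: float = 20.0
    edge_smoothing_vox: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(s < 16 for s in self.size):
            raise ValueError(f"size must be >= 16 per axis, got {self.size}")
        if len(set(self.means)) != len(self.means):
            raise ValueError("structure means must be distinct")
        if self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("noise and bias amplitudes must be non-negative")


def make_phantom(spec: PhantomSpec) -> tuple[Volume, LabelVolume]:
    """Build the intensity volume and its structure label map."""
    dims = np.asarray(spec.size)
    spacing = np.asarray(spec.spacing, dtype=np.float64)
    half = (dims - 1) / 2.0 * spacing
    center = half.copy()
    coords = np.indices(spec.size, dtype=np.float64)
    world = coords * spacing[:, None, None, None]

    labels = np.zeros(spec.size, dtype=np.int32)
    centers = [center, center, center + np.asarray(_CORE_OFFSET) * half]
    for k, (axes, c) in enumerate(zip(_SEMI_AXES, centers), start=1):
        semi = np.asarray(axes) * half
        d2 = sum(
            ((world[ax] - c[ax]) / semi[ax]) ** 2 for ax in range(3)
        )
        labels[d2 <= 1.0] = k

    intensity = np.zeros(spec.size, dtype=np.float64)
    for k, mean in enumerate(spec.means, start=1):
        intensity[labels == k] = mean
    if spec.edge_smoothing_vox > 0:
        intensity = ndimage.gaussian_filter(intensity, spec.edge_smoothing_vox)

    rng = np.random.default_rng(spec.seed)
    if spec.bias_amplitude > 0:
        raw = rng.standard_normal(spec.size)
        smooth = ndimage.gaussian_filter(raw, spec.bias_smoothness_mm / spacing)
        peak = np.abs(smooth).max()
        if peak > 0:
            smooth /= peak
        intensity *= 1.0 + spec.bias_amplitude * smooth
    if spec.noise_sd > 0:
        intensity += rng.normal(0.0, spec.noise_sd, spec.size)

    origin = np.zeros(3)
    return (
        Volume(intensity, spacing, origin),
        LabelVolume(labels, spacing, origin),
    )


def apply_known_affine(volume: Volume, labels: LabelVolume, params,
                       seed: int = 0, min_overlap: float = 0.6):
    """Move a phantom by a known affine, returning the ground truth.

    The moved volume is resampled through the inverse map, J(x) =
    I(T^-1(x)), so registering moved -> original recovers ``params``
    (12-vector: translations mm, rotations rad, scales, shears, composed
    about the volume center).  Labels move by nearest neighbor; voxels whose
    source point leaves the original extent become 0/background.
    """
    del seed  # the operation is deterministic; kept for interface symmetry
    t_gt = AffineTransform.from_params(params, center=volume.center_world)
    inv = t_gt.inverse()
    pts = volume.voxel_centers_world()
    src = inv.apply(pts)
    idx = volume.world_to_index(src)
    dims = np.asarray(volume.shape, dtype=np.float64)
    inside = np.all((idx >= 0.0) & (idx <= (dims - 1.0)[:, None]), axis=0)
    frac = float(inside.mean())
    if frac < min_overlap:
        raise ValueError(
            f"transform keeps only {frac:.0%} overlap (< {min_overlap:.0%})"
        )
    moved = ndimage.map_coordinates(volume.data, idx, order=1,
                                    mode="constant", cval=0.0)
    moved_labels = ndimage.map_coordinates(labels.data, idx, order=0,
                                           mode="constant", cval=0)
    return (
        Volume(moved.reshape(volume.shape), volume.spacing.copy(), volume.origin.copy()),
        LabelVolume(moved_labels.reshape(volume.shape).astype(np.int32),
                    labels.spacing.copy(), labels.origin.copy()),
        t_gt,
    )


def apply_known_deformation(volume: Volume, labels: LabelVolume,
                            amplitude_mm: float, smoothness_mm: float,
                            seed: int = 0):
    """Deform a phantom by a known smooth random field.

    The field is Gaussian-filtered white noise rescaled so each component's
    maximum magnitude equals ``amplitude_mm`` — smooth, seeded and bounded.
    Requires amplitude <= smoothness/2, which keeps the warp invertible in
    practice.  The moved image samples the original at x + u(x); the
    generating field is returned for error measurement.
    """
    if amplitude_mm < 0 or smoothness_mm <= 0:
        raise ValueError("amplitude must be >= 0 and smoothness > 0")
    if amplitude_mm > smoothness_mm / 2.0:
        raise ValueError(
            f"amplitude {amplitude_mm} exceeds smoothness/2 = {smoothness_mm / 2}"
        )
    rng = np.random.default_rng(seed)
    spacing = volume.spacing
    vec = np.zeros((*volume.shape, 3))
    if amplitude_mm > 0:
        for k in range(3):
            raw = rng.standard_normal(volume.shape)
            smooth = ndimage.gaussian_filter(raw, smoothness_mm / spacing)
            peak = np.abs(smooth).max()
            if peak > 0:
                vec[..., k] = smooth / peak * amplitude_mm
    gt_field = DisplacementField(vec, spacing)

    idx = np.indices(volume.shape, dtype=np.float64)
    coords = (idx + np.moveaxis(vec, -1, 0) / spacing[:, None, None, None]).reshape(3, -1)
    moved = ndimage.map_coordinates(volume.data, coords, order=1, mode="nearest")
    moved_labels = ndimage.map_coordinates(labels.data, coords, order=0, mode="nearest")
    return (
        Volume(moved.reshape(volume.shape), spacing.copy(), volume.origin.copy()),
        LabelVolume(moved_labels.reshape(volume.shape).astype(np.int32),
                    labels.spacing.copy(), labels.origin.copy()),
        gt_field,
    )
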