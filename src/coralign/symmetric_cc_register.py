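"""Simplified symmetric deformable refinement driven by local CC.

Two half-way displacement fields phi1, phi2 warp the reference and the
moving image toward a common midpoint (I_T = I o phi1, J_T = J o phi2).
Each iteration evaluates the local CC map between the two half-warped
images, forms a voxelwise ascent direction from the CC derivative with
respect to each image's intensity (for cc = C^2/(A B) at the window
centered on x:  d cc / d J(x) = 2C/(AB) (Ibar - (C/B) Jbar), and the
mirror-image expression for I), projects it onto the image gradients,
smooths the update, and applies equal-and-opposite half-steps to the two
fields.  Steps that fail to increase the mean local CC are rejected, so
the accepted trace is non-decreasing by construction.

This greedy scheme is a deliberate surrogate for time-integrated
velocity-field optimization: the metric (the exact A/B/C local CC) and the
monotone-improvement contract are pinned down; the optimizer is the
simplest symmetric method honoring them.  Diffeomorphism is not enforced —
the Jacobian of the recovered warp is logged, not constrained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import cc_metric
from .affine_register import AffineTransform
from .cr_metric import sample_transformed
from .volume_io import Volume, _block_mean

__all__ = [
    "DisplacementField",
    "SymConfig",
    "warp",
    "symmetric_step",
    "register_symmetric",
    "invert_field",
    "compose_midpoint_warp",
    "read_field",
    "write_field",
]


@dataclass
class DisplacementField:
    """Per-voxel displacement u(x) in mm on the reference grid.

    A warped image samples the source at x + u(x); the zero field is the
    identity warp.
    """

    vectors: np.ndarray  # shape (nx, ny, nz, 3), mm
    spacing: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(f"expected (nx,ny,nz,3) vectors, got {self.vectors.shape}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite displacements")

    @classmethod
    def zero(cls, shape, spacing) -> "DisplacementField":
        return cls(np.zeros((*shape, 3)), spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    def max_displacement_mm(self) -> float:
        return float(np.abs(self.vectors).max())


@dataclass
class SymConfig:
    """Greedy symmetric refinement settings.

    step_vox is the largest per-iteration half-step (voxels); the update and
    the accumulated fields are smoothed with Gaussian kernels of the given
    widths (mm).  levels lists pyramid downsampling factors, coarse first.
    """

    radius: int = cc_metric.DEFAULT_RADIUS
    iterations: int = 40
    step_vox: float = 0.25
    update_sigma_mm: float = 3.0
    field_sigma_mm: float = 1.5
    levels: tuple[int, ...] = (2, 1)
    cc_tol: float = 1e-6
    min_step_vox: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if min(self.step_vox, self.update_sigma_mm, self.field_sigma_mm) <= 0:
            raise ValueError("steps and smoothing widths must be positive")


def warp(volume: Volume, field: DisplacementField) -> Volume:
    """Sample the volume at x + u(x) with trilinear interpolation.

    Out-of-extent samples clamp to the nearest edge value.
    """
    if field.shape != volume.shape:
        raise ValueError(f"field shape {field.shape} != volume shape {volume.shape}")
    idx = np.indices(volume.shape, dtype=np.float64)
    coords = idx + np.moveaxis(field.vectors, -1, 0) / volume.spacing[:, None, None, None]
    data = ndimage.map_coordinates(volume.data, coords.reshape(3, -1), order=1, mode="nearest")
    return Volume(data.reshape(volume.shape), volume.spacing.copy(), volume.origin.copy())


def _smooth_field(vectors: np.ndarray, sigma_mm: float, spacing: np.ndarray) -> np.ndarray:
    sig = sigma_mm / spacing
    out = np.empty_like(vectors)
    for k in range(3):
        out[..., k] = ndimage.gaussian_filter(vectors[..., k], sigma=sig)
    return out


def _mean_cc_between(a: Volume, b: Volume, radius: int) -> tuple[float, cc_metric.CCMap, cc_metric.CCIntermediates]:
    sums = cc_metric.window_sums(a, b, radius)
    inter = cc_metric.cc_intermediates(sums)
    ccm = cc_metric.cc_map(inter)
    if not ccm.valid.any():
        return 0.0, ccm, inter
    return cc_metric.mean_cc(ccm), ccm, inter


def symmetric_step(fixed: Volume, moving: Volume,
                   phi1: DisplacementField, phi2: DisplacementField,
                   config: SymConfig):
    """One greedy symmetric update of the two half-way fields.

    Returns ``(phi1', phi2', mean_cc)``.  If the trial step does not
    increase the mean local CC (or the step length is zero), the input
    fields are returned unchanged with the current mean CC.
    """
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must be co-dimensioned")
    i_t = warp(fixed, phi1)
    j_t = warp(moving, phi2)
    cc_before, ccm, inter = _mean_cc_between(i_t, j_t, config.radius)
    if config.step_vox == 0.0:
        return phi1, phi2, cc_before

    a, b, c = inter.a, inter.b, inter.c
    denom = a * b
    safe = ccm.valid
    ibar = i_t.data - inter.mean_i
    jbar = j_t.data - inter.mean_j
    g_i = np.zeros_like(a)
    g_j = np.zeros_like(a)
    # d cc / d I(x) and d cc / d J(x) at the window centered on x
    g_i[safe] = 2.0 * c[safe] / denom[safe] * (jbar[safe] - c[safe] / a[safe] * ibar[safe])
    g_j[safe] = 2.0 * c[safe] / denom[safe] * (ibar[safe] - c[safe] / b[safe] * jbar[safe])

    grad_i = np.stack(np.gradient(i_t.data, *fixed.spacing), axis=-1)
    grad_j = np.stack(np.gradient(j_t.data, *fixed.spacing), axis=-1)
    force1 = g_i[..., None] * grad_i
    force2 = g_j[..., None] * grad_j
    force1 = _smooth_field(force1, config.update_sigma_mm, fixed.spacing)
    force2 = _smooth_field(force2, config.update_sigma_mm, fixed.spacing)

    peak = max(np.abs(force1).max(), np.abs(force2).max())
    if peak == 0.0:
        return phi1, phi2, cc_before
    # equal-and-opposite half-steps, each capped at step_vox/2 voxels
    scale = 0.5 * config.step_vox * float(fixed.spacing.min()) / peak
    v1 = _smooth_field(phi1.vectors + scale * force1, config.field_sigma_mm, fixed.spacing)
    v2 = _smooth_field(phi2.vectors + scale * force2, config.field_sigma_mm, fixed.spacing)
    trial1 = DisplacementField(v1, phi1.spacing)
    trial2 = DisplacementField(v2, phi2.spacing)
    cc_after, _, _ = _mean_cc_between(warp(fixed, trial1), warp(moving, trial2), config.radius)
    if cc_after > cc_before:
        return trial1, trial2, cc_after
    return phi1, phi2, cc_before


def invert_field(field: DisplacementField, max_iter: int = 20,
                 tol_vox: float = 1e-3) -> DisplacementField:
    """Fixed-point inversion: find v with v(x) = -u(x + v(x))."""
    u = field.vectors
    spacing = field.spacing
    idx = np.indices(field.shape, dtype=np.float64)
    v = np.zeros_like(u)
    for _ in range(max_iter):
        coords = idx + np.moveaxis(v, -1, 0) / spacing[:, None, None, None]
        flat = coords.reshape(3, -1)
        u_at = np.stack(
            [ndimage.map_coordinates(u[..., k], flat, order=1, mode="nearest")
             for k in range(3)],
            axis=-1,
        ).reshape(u.shape)
        v_new = -u_at
        resid = np.abs(v_new - v).max() / spacing.min()
        v = v_new
        if resid < tol_vox:
            break
    return DisplacementField(v, spacing)


def compose_midpoint_warp(phi1: DisplacementField, phi2: DisplacementField) -> DisplacementField:
    """Full reference->moving displacement from the two half-way fields.

    With I_T(x) = I(x + u1(x)) and J_T(x) = J(x + u2(x)) aligned at the
    midpoint, the composed map sends reference voxel x through the inverse
    of phi1 and then through phi2:  u(x) = v(x) + u2(x + v(x)), where v is
    the inverse displacement of u1.
    """
    v = invert_field(phi1)
    spacing = phi1.spacing
    idx = np.indices(phi1.shape, dtype=np.float64)
    coords = (idx + np.moveaxis(v.vectors, -1, 0) / spacing[:, None, None, None]).reshape(3, -1)
    u2_at = np.stack(
        [ndimage.map_coordinates(phi2.vectors[..., k], coords, order=1, mode="nearest")
         for k in range(3)],
        axis=-1,
    ).reshape(phi2.vectors.shape)
    return DisplacementField(v.vectors + u2_at, spacing)


def _downsample_volume(volume: Volume, factor: int) -> Volume:
    if factor == 1:
        return volume
    out = volume
    for _ in range(int(np.log2(factor))):
        data = _block_mean(out.data, 2)
        out = Volume(data, out.spacing * 2, out.origin + 0.5 * out.spacing)
    return out


def _upsample_field(field: DisplacementField, target_shape, target_spacing) -> DisplacementField:
    src_dims = np.asarray(field.shape, dtype=np.float64)
    dst_dims = np.asarray(target_shape, dtype=np.float64)
    idx = np.indices(target_shape, dtype=np.float64).reshape(3, -1)
    # map fine voxel centers into coarse index space (same physical frame)
    ratio = (np.asarray(target_spacing) / field.spacing)[:, None]
    coords = idx * ratio + 0.5 * (ratio - 1.0)
    np.clip(coords, 0.0, (src_dims - 1.0)[:, None], out=coords)
    vec = np.stack(
        [ndimage.map_coordinates(field.vectors[..., k], coords, order=1, mode="nearest")
         for k in range(3)],
        axis=-1,
    ).reshape((*target_shape, 3))
    return DisplacementField(vec, np.asarray(target_spacing, dtype=np.float64))


def resample_through_affine(moving: Volume, transform: AffineTransform,
                            reference: Volume) -> Volume:
    """Moving image resampled onto the reference grid through an affine."""
    values, _ = sample_transformed(moving, transform, reference)
    return Volume(values, reference.spacing.copy(), reference.origin.copy())


def register_symmetric(reference: Volume, moving: Volume,
                       init: AffineTransform | None = None,
                       config: SymConfig | None = None):
    """Coarse-to-fine greedy symmetric CC registration.

    Returns ``(phi1, phi2, warped, trace)``: the two half-way fields on the
    reference grid, the moving image carried through the composed warp onto
    the reference grid, and a dict with the accepted mean-CC trace (one
    non-decreasing series over all levels) plus the Jacobian-determinant
    range of the composed warp.
    """
    config = config or SymConfig()
    if reference.shape != moving.shape and init is None:
        raise ValueError("shapes differ; supply an affine init to resample first")
    mov = resample_through_affine(moving, init, reference) if init is not None else moving

    level_traces: list[list[float]] = []
    phi1 = phi2 = None
    for level in config.levels:
        ref_l = _downsample_volume(reference, level)
        mov_l = _downsample_volume(mov, level)
        radius = max(1, min(config.radius, min(ref_l.shape) // 2))
        level_cfg = SymConfig(
            radius=radius, iterations=config.iterations, step_vox=config.step_vox,
            update_sigma_mm=config.update_sigma_mm, field_sigma_mm=config.field_sigma_mm,
            levels=config.levels, cc_tol=config.cc_tol,
            min_step_vox=config.min_step_vox, seed=config.seed,
        )
        if phi1 is None:
            phi1 = DisplacementField.zero(ref_l.shape, ref_l.spacing)
            phi2 = DisplacementField.zero(ref_l.shape, ref_l.spacing)
        else:
            phi1 = _upsample_field(phi1, ref_l.shape, ref_l.spacing)
            phi2 = _upsample_field(phi2, ref_l.shape, ref_l.spacing)
        step = config.step_vox
        cc_trace: list[float] = []
        for _ in range(config.iterations):
            level_cfg.step_vox = step
            new1, new2, cc_now = symmetric_step(ref_l, mov_l, phi1, phi2, level_cfg)
            if new1 is not phi1:  # accepted: mean CC strictly increased
                phi1, phi2 = new1, new2
                cc_trace.append(cc_now)
            else:
                if not cc_trace:
                    cc_trace.append(cc_now)
                step *= 0.5
                if step < config.min_step_vox:
                    break
        level_traces.append(cc_trace)

    composed = compose_midpoint_warp(phi1, phi2)
    warped = warp(mov, composed)
    jac = _jacobian_determinant(composed)
    trace = {
        # mean CC is grid-dependent, so each level owns its accepted trace;
        # every per-level series is non-decreasing by construction
        "mean_cc": level_traces[-1],
        "mean_cc_per_level": level_traces,
        "jacobian_min": float(jac.min()),
        "jacobian_max": float(jac.max()),
    }
    return phi1, phi2, warped, trace


def _jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """det of d(x + u)/dx, logged to flag folding (not enforced)."""
    grads = [np.gradient(field.vectors[..., k], *field.spacing) for k in range(3)]
    jac = np.zeros((*field.shape, 3, 3))
    for k in range(3):
        for ax in range(3):
            jac[..., k, ax] = grads[k][ax]
        jac[..., k, k] += 1.0
    return np.linalg.det(jac)


def write_field(field: DisplacementField, path) -> None:
    """Store as a NIfTI with a trailing 3-component dimension."""
    import nibabel as nib

    aff = np.diag(np.append(field.spacing, 1.0))
    img = nib.Nifti1Image(field.vectors.astype(np.float32), aff)
    nib.save(img, str(path))


def read_field(path) -> DisplacementField:
    import nibabel as nib

    img = nib.load(str(path))
    vec = np.asanyarray(img.dataobj).astype(np.float64)
    if vec.ndim != 4 or vec.shape[-1] != 3:
        raise ValueError(f"{path}: expected a (nx,ny,nz,3) field, got {vec.shape}")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
    return DisplacementField(vec, spacing)
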