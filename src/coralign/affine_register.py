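"""Multistart multiresolution affine registration minimizing 1 - CR.

The search runs over a 4-level pyramid (8, 4, 2, 1 mm).  Both images are
first resampled to a 1 mm isotropic grid and block-averaged down.  At the
8 mm stage a coarse multistart grid over rotations and translations seeds
the search; the best few candidates are locally optimized and survivors are
refined through the 4, 2 and 1 mm stages.  Each stage bins its reference
level with 256/n bins (n the stage spacing in mm: 32, 64, 128, 256 bins)
and builds the sorted intensity index exactly once; every candidate
transform at that stage reuses it.

The local optimizer is a deterministic, derivative-free coordinate-wise
line search with step halving; accepted steps never increase the cost
1 - eta(J_T | I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from . import cr_metric
from .volume_io import Volume, build_pyramid, resample_isotropic

__all__ = [
    "AffineTransform",
    "SearchConfig",
    "WORST_COST",
    "compose",
    "cost",
    "register_affine",
    "bins_for_stage",
    "read_transform",
    "write_transform",
]

WORST_COST = 2.0  # sentinel: any real cost 1 - eta lies in [0, 1]

# parameter vector layout: [tx ty tz | rx ry rz | sx sy sz | hxy hxz hyz]
_T, _R, _S, _H = slice(0, 3), slice(3, 6), slice(6, 9), slice(9, 12)


def _euler_to_matrix(angles: np.ndarray) -> np.ndarray:
    # extrinsic x-y-z order: R = Rz(rz) @ Ry(ry) @ Rx(rx)
    return Rotation.from_euler("xyz", angles).as_matrix()


def _matrix_to_euler(rot: np.ndarray) -> np.ndarray:
    return Rotation.from_matrix(rot).as_euler("xyz")


@dataclass
class AffineTransform:
    """A 4x4 homogeneous world-coordinate (mm) map, last row (0,0,0,1).

    The 12-parameter form is 3 translations (mm), 3 rotations (radians,
    extrinsic x-y-z), 3 scales and 3 shears, composed about an optional
    center c as  T(t) . T(c) . R . Shear . Scale . T(-c),  so parameters are
    invariant to voxel anisotropy (the map acts on world coordinates).
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64).reshape(4, 4)
        if not np.allclose(m[3], [0, 0, 0, 1]):
            raise ValueError("last row of an affine matrix must be (0,0,0,1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("singular affine matrix")
        self.matrix = m

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_params(cls, params, center=None) -> "AffineTransform":
        p = np.zeros(12)
        p[_S] = 1.0
        p[: len(np.atleast_1d(params))] = params
        rot = _euler_to_matrix(p[_R])
        shear = np.eye(3)
        shear[0, 1], shear[0, 2], shear[1, 2] = p[_H]
        scale = np.diag(p[_S])
        lin = rot @ shear @ scale
        c = np.zeros(3) if center is None else np.asarray(center, dtype=np.float64)
        m = np.eye(4)
        m[:3, :3] = lin
        m[:3, 3] = p[_T] + c - lin @ c
        return cls(m)

    def to_params(self, center=None) -> np.ndarray:
        """Decompose back to the 12 parameters (scales assumed positive)."""
        lin = self.matrix[:3, :3]
        q, u = np.linalg.qr(lin)
        sign = np.sign(np.diag(u))
        sign[sign == 0] = 1.0
        q = q * sign
        u = sign[:, None] * u
        scales = np.diag(u).copy()
        # Shear @ Scale is upper triangular with columns scaled, so each
        # shear entry divides by its column's scale
        shears = np.array([u[0, 1] / scales[1], u[0, 2] / scales[2], u[1, 2] / scales[2]])
        angles = _matrix_to_euler(q)
        c = np.zeros(3) if center is None else np.asarray(center, dtype=np.float64)
        t = self.matrix[:3, 3] - c + lin @ c
        return np.concatenate([t, angles, scales, shears])

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map world points of shape (3, N)."""
        return self.matrix[:3, :3] @ points + self.matrix[:3, 3:4]


def compose(a: AffineTransform, b: AffineTransform) -> AffineTransform:
    """The map x -> a(b(x))."""
    return AffineTransform(a.matrix @ b.matrix)


def write_transform(transform: AffineTransform, path) -> None:
    """4 lines x 4 whitespace-separated numbers."""
    np.savetxt(str(path), transform.matrix, fmt="%.12g")


def read_transform(path) -> AffineTransform:
    return AffineTransform(np.loadtxt(str(path)).reshape(4, 4))


def bins_for_stage(stage_mm: int) -> int:
    """Histogram bins at resolution n mm: 256/n (32, 64, 128, 256)."""
    if stage_mm not in (8, 4, 2, 1):
        raise ValueError(f"stage must be one of 8/4/2/1 mm, got {stage_mm}")
    return 256 // stage_mm


@dataclass
class SearchConfig:
    """Knobs of the multistart multiresolution search.

    Defaults: rotations +/-45 deg in 15 deg steps per axis and translations
    +/-16 mm in 8 mm steps at the 8 mm multistart, keeping the best 3
    candidates; rigid (6 dof) search at 8 mm, the configured dof from 4 mm
    on.  The seed feeds optional perturbation restarts (none by default, so
    the search is fully deterministic).
    """

    dof: int = 12
    rot_range_deg: float = 45.0
    rot_step_deg: float = 15.0
    trans_range_mm: float = 16.0
    trans_step_mm: float = 8.0
    n_keep: int = 3
    max_sweeps: int = 30
    cost_tol: float = 1e-7
    min_overlap_frac: float = 0.3
    # plausible anatomical ranges; unconstrained scales let the search
    # collapse onto the homogeneous image interior (zoom pathology)
    scale_bounds: tuple[float, float] = (0.75, 1.35)
    shear_bound: float = 0.25
    levels_mm: tuple[int, ...] = (8, 4, 2, 1)
    seed: int = 0

    def __post_init__(self):
        if self.dof not in (6, 9, 12):
            raise ValueError(f"dof must be 6, 9 or 12, got {self.dof}")
        if min(self.rot_range_deg, self.rot_step_deg,
               self.trans_range_mm, self.trans_step_mm) <= 0:
            raise ValueError("search ranges and steps must be positive")


def cost(transform: AffineTransform, reference_level: Volume, moving: Volume,
         index: cr_metric.SortedIntensityIndex, min_overlap_frac: float = 0.05) -> float:
    """1 - eta(J_T | I) at this transform; degenerate cases -> worst cost."""
    try:
        values, overlap = cr_metric.sample_transformed(moving, transform, reference_level)
    except cr_metric.CRError:
        return WORST_COST
    n_needed = max(2, int(min_overlap_frac * overlap.size))
    if int(overlap.sum()) < n_needed:
        return WORST_COST
    stats = cr_metric.accumulate_bin_stats(index, values, overlap)
    try:
        result = cr_metric.correlation_ratio(stats)
    except cr_metric.CRError:
        return WORST_COST
    return 1.0 - result.eta


def _active_params(dof: int, stage_mm: int) -> list[int]:
    # rigid at the coarsest stage; scales from dof>=9, shears at dof 12
    if stage_mm == 8:
        return list(range(6))
    active = list(range(6))
    if dof >= 9:
        active += [6, 7, 8]
    if dof == 12:
        active += [9, 10, 11]
    return active


def _initial_steps(stage_mm: int) -> np.ndarray:
    steps = np.empty(12)
    steps[_T] = float(stage_mm)
    steps[_R] = 0.01 * stage_mm          # radians
    steps[_S] = 0.02
    steps[_H] = 0.02
    return steps


_MIN_STEPS = np.array([0.05] * 3 + [5e-4] * 3 + [1e-3] * 3 + [1e-3] * 3)


def _coordinate_descent(cost_fn, params, active, steps, max_sweeps, cost_tol,
                        bounds=None):
    """Greedy per-parameter line search with step halving.

    Accepted moves strictly decrease the cost, so the trace of accepted
    costs is non-increasing by construction.  ``bounds`` maps parameter
    index -> (lo, hi); trials outside their bounds are never evaluated.
    """
    params = np.asarray(params, dtype=np.float64).copy()
    steps = steps.copy()
    bounds = bounds or {}

    def in_bounds(p, k):
        lo, hi = bounds.get(k, (-np.inf, np.inf))
        return lo <= p[k] <= hi

    best = cost_fn(params)
    trace = [best]
    for _ in range(max_sweeps):
        improved = False
        for k in active:
            for direction in (+1.0, -1.0):
                trial = params.copy()
                trial[k] += direction * steps[k]
                if not in_bounds(trial, k):
                    continue
                c = cost_fn(trial)
                if c < best - cost_tol:
                    params, best = trial, c
                    trace.append(best)
                    improved = True
                    # keep walking while the same move keeps helping
                    while True:
                        trial = params.copy()
                        trial[k] += direction * steps[k]
                        if not in_bounds(trial, k):
                            break
                        c = cost_fn(trial)
                        if c < best - cost_tol:
                            params, best = trial, c
                            trace.append(best)
                        else:
                            break
                    break
        if not improved:
            steps = steps / 2.0
            if np.all(steps[active] < _MIN_STEPS[active]):
                break
    return params, best, trace


def register_affine(reference: Volume, moving: Volume,
                    config: SearchConfig | None = None):
    """Recover the affine transform aligning ``moving`` to ``reference``.

    Returns ``(AffineTransform, trace)`` where the trace lists, per stage,
    the number of bins, the best cost and the accepted-cost history of the
    winning candidate.  The returned transform maps reference world
    coordinates into the moving image (J_T = J o T).
    """
    config = config or SearchConfig()
    ref1 = reference if np.allclose(reference.spacing, 1.0, atol=1e-6) \
        else resample_isotropic(reference, 1.0)
    mov1 = moving if np.allclose(moving.spacing, 1.0, atol=1e-6) \
        else resample_isotropic(moving, 1.0)
    pyr_ref = build_pyramid(ref1)
    pyr_mov = build_pyramid(mov1)
    center = ref1.center_world

    rot_vals = np.deg2rad(
        np.arange(-config.rot_range_deg, config.rot_range_deg + 1e-9, config.rot_step_deg)
    )
    tr_vals = np.arange(
        -config.trans_range_mm, config.trans_range_mm + 1e-9, config.trans_step_mm
    )

    trace = []
    candidates: list[np.ndarray] = []
    finite_seen = False

    for stage_mm in config.levels_mm:
        ref_level = pyr_ref.level(stage_mm)
        mov_level = pyr_mov.level(stage_mm)
        n_bins = bins_for_stage(stage_mm)
        binned = cr_metric.bin_reference(ref_level, n_bins)
        builds_before = cr_metric.build_sorted_index.counter
        index = cr_metric.build_sorted_index(binned)

        def stage_cost(p):
            t = AffineTransform.from_params(p, center=center)
            return cost(t, ref_level, mov_level, index, config.min_overlap_frac)

        if stage_mm == config.levels_mm[0]:
            # coarse multistart: rigid grid over rotations x translations
            scored = []
            base = np.zeros(12)
            base[_S] = 1.0
            for rx in rot_vals:
                for ry in rot_vals:
                    for rz in rot_vals:
                        for tx in tr_vals:
                            for ty in tr_vals:
                                for tz in tr_vals:
                                    p = base.copy()
                                    p[:6] = (tx, ty, tz, rx, ry, rz)
                                    scored.append((stage_cost(p), p))
            # tie-break equal costs by preferring the smallest motion, so
            # degenerate coarse stages (few voxels per bin) stay deterministic
            # and self-registration seeds from the identity
            scored.sort(
                key=lambda cp: (round(cp[0] / config.cost_tol),
                                float(np.abs(cp[1][:3]).sum() + 50.0 * np.abs(cp[1][3:6]).sum()))
            )
            candidates = [p for _, p in scored[: config.n_keep]]

        steps = _initial_steps(stage_mm)
        active = _active_params(config.dof, stage_mm)
        lo_s, hi_s = config.scale_bounds
        bounds = {k: (lo_s, hi_s) for k in (6, 7, 8)}
        bounds.update({k: (-config.shear_bound, config.shear_bound) for k in (9, 10, 11)})
        optimized = []
        for p in candidates:
            p_opt, c_opt, c_trace = _coordinate_descent(
                stage_cost, p, active, steps, config.max_sweeps, config.cost_tol,
                bounds=bounds,
            )
            optimized.append((c_opt, p_opt, c_trace))
        optimized.sort(key=lambda item: item[0])
        if optimized[0][0] < WORST_COST:
            finite_seen = True
        # survivors: keep the full set through the first refinement stage,
        # then commit to the single best candidate
        if stage_mm in config.levels_mm[:1]:
            candidates = [p for _, p, _ in optimized]
        else:
            candidates = [optimized[0][1]]
        trace.append({
            "stage_mm": stage_mm,
            "n_bins": n_bins,
            "index_builds": cr_metric.build_sorted_index.counter - builds_before,
            "best_cost": optimized[0][0],
            "accepted_costs": optimized[0][2],
        })

    if not finite_seen:
        raise cr_metric.CRError("no stage produced a finite cost (disjoint extents?)")
    best_params = candidates[0]
    return AffineTransform.from_params(best_params, center=center), trace
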