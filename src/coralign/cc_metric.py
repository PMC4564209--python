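"""Local windowed cross-correlation via five running window sums.

For two co-registered images I_T and J_T, the local CC at voxel x is the
squared correlation over a cubic (2r+1)^3 window centered at x::

    CC(x) = C(x)^2 / (A(x) * B(x))

with the centered intermediates assembled from five neighborhood sums
(sum I, sum J, sum I^2, sum J^2, sum I*J):

    A(x) = sum I^2 - 2 m_I sum I + n m_I^2     (= sum (I - m_I)^2)
    B(x) = sum J^2 - 2 m_J sum J + n m_J^2
    C(x) = sum I*J - m_I sum J - m_J sum I + n m_I m_J

where m_I, m_J are the window means and n = (2r+1)^3.  The window sums are
computed with separable running box sums (add the entering slab, drop the
departing one), never by fresh per-voxel loops; :func:`cc_map_direct` is the
per-voxel brute-force oracle.  Boundaries are edge-replicated so n is the
same at every voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import Volume

__all__ = [
    "WindowSums",
    "CCIntermediates",
    "CCMap",
    "DEFAULT_RADIUS",
    "MAX_RADIUS",
    "window_sums",
    "cc_intermediates",
    "cc_map",
    "cc_map_direct",
    "mean_cc",
]

DEFAULT_RADIUS = 5   # the customary neighborhood radius
MAX_RADIUS = 8       # hard ceiling on r


@dataclass
class WindowSums:
    s_i: np.ndarray
    s_j: np.ndarray
    s_ii: np.ndarray
    s_jj: np.ndarray
    s_ij: np.ndarray
    radius: int

    @property
    def n(self) -> int:
        """Window voxel count (2r+1)^3, constant under edge replication."""
        return (2 * self.radius + 1) ** 3


@dataclass
class CCIntermediates:
    mean_i: np.ndarray
    mean_j: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    n: int


@dataclass
class CCMap:
    cc: np.ndarray      # in [0, 1]; 0 where invalid
    valid: np.ndarray   # both window patches non-degenerate


def _running_box_sum(data: np.ndarray, r: int) -> np.ndarray:
    """Separable (2r+1)^3 box sum with edge replication.

    Along each axis a prefix sum of the edge-padded array turns the window
    sum into two lookups: the slab entering the window minus the one leaving
    it — the incremental-reuse scheme.
    """
    out = np.asarray(data, dtype=np.float64)
    w = 2 * r + 1
    for ax in range(3):
        padded = np.pad(out, [(r, r) if a == ax else (0, 0) for a in range(3)], mode="edge")
        csum = np.cumsum(padded, axis=ax, dtype=np.float64)
        zeros_shape = list(csum.shape)
        zeros_shape[ax] = 1
        csum = np.concatenate([np.zeros(zeros_shape), csum], axis=ax)
        n = out.shape[ax]
        hi = [slice(None)] * 3
        lo = [slice(None)] * 3
        hi[ax] = slice(w, w + n)
        lo[ax] = slice(0, n)
        out = csum[tuple(hi)] - csum[tuple(lo)]
    return out


def _check_radius(radius: int, shape) -> None:
    if not (1 <= radius <= MAX_RADIUS):
        raise ValueError(f"radius must be in [1, {MAX_RADIUS}], got {radius}")
    if radius > min(shape) // 2:
        raise ValueError(
            f"radius {radius} exceeds half the smallest dimension of {shape}"
        )


def window_sums(fixed: Volume, moving_warped: Volume, radius: int = DEFAULT_RADIUS) -> WindowSums:
    """Compute the five (2r+1)^3 neighborhood sums for both images."""
    f = np.asarray(getattr(fixed, "data", fixed), dtype=np.float64)
    g = np.asarray(getattr(moving_warped, "data", moving_warped), dtype=np.float64)
    if f.shape != g.shape:
        raise ValueError(f"shape mismatch {f.shape} vs {g.shape}")
    _check_radius(radius, f.shape)
    return WindowSums(
        s_i=_running_box_sum(f, radius),
        s_j=_running_box_sum(g, radius),
        s_ii=_running_box_sum(f * f, radius),
        s_jj=_running_box_sum(g * g, radius),
        s_ij=_running_box_sum(f * g, radius),
        radius=radius,
    )


def cc_intermediates(sums: WindowSums) -> CCIntermediates:
    """Assemble the window means and the centered A, B, C grids."""
    n = sums.n
    mean_i = sums.s_i / n
    mean_j = sums.s_j / n
    a = sums.s_ii - 2.0 * mean_i * sums.s_i + n * mean_i**2
    b = sums.s_jj - 2.0 * mean_j * sums.s_j + n * mean_j**2
    c = sums.s_ij - mean_i * sums.s_j - mean_j * sums.s_i + n * mean_i * mean_j
    return CCIntermediates(mean_i=mean_i, mean_j=mean_j, a=a, b=b, c=c, n=n)


def cc_map(inter: CCIntermediates, eps: float | None = None) -> CCMap:
    """CC = C^2 / (A*B), clamped to [0, 1]; flat patches are invalid (cc 0).

    ``eps`` guards the denominator; the default 1e-12 * n scales with the
    window size.  A and B are centered sums of squares, so any patch whose
    product falls below eps carries no usable correlation signal.
    """
    if eps is None:
        eps = 1e-12 * inter.n
    denom = inter.a * inter.b
    valid = denom > eps
    cc = np.zeros_like(denom)
    cc[valid] = inter.c[valid] ** 2 / denom[valid]
    np.clip(cc, 0.0, 1.0, out=cc)
    return CCMap(cc=cc, valid=valid)


def cc_map_direct(fixed, moving_warped, radius: int = DEFAULT_RADIUS,
                  eps: float | None = None) -> CCMap:
    """Brute-force oracle: recompute each voxel's CC from scratch.

    Visits every voxel independently and sums over its edge-replicated
    window with fresh loops; no running sums are shared between voxels.
    """
    f = np.asarray(getattr(fixed, "data", fixed), dtype=np.float64)
    g = np.asarray(getattr(moving_warped, "data", moving_warped), dtype=np.float64)
    if f.shape != g.shape:
        raise ValueError(f"shape mismatch {f.shape} vs {g.shape}")
    _check_radius(radius, f.shape)
    r = radius
    n = (2 * r + 1) ** 3
    if eps is None:
        eps = 1e-12 * n
    fp = np.pad(f, r, mode="edge")
    gp = np.pad(g, r, mode="edge")
    cc = np.zeros(f.shape)
    valid = np.zeros(f.shape, dtype=bool)
    w = 2 * r + 1
    for ix in range(f.shape[0]):
        for iy in range(f.shape[1]):
            for iz in range(f.shape[2]):
                wf = fp[ix:ix + w, iy:iy + w, iz:iz + w].ravel()
                wg = gp[ix:ix + w, iy:iy + w, iz:iz + w].ravel()
                df = wf - wf.mean()
                dg = wg - wg.mean()
                a = float(df @ df)
                b = float(dg @ dg)
                c = float(df @ dg)
                if a * b > eps:
                    valid[ix, iy, iz] = True
                    cc[ix, iy, iz] = min(max(c * c / (a * b), 0.0), 1.0)
    return CCMap(cc=cc, valid=valid)


def mean_cc(cc: CCMap, mask: np.ndarray | None = None) -> float:
    """Mean local CC over valid (and optionally masked) voxels."""
    sel = cc.valid if mask is None else (cc.valid & np.asarray(mask, dtype=bool))
    if not sel.any():
        raise ValueError("no valid voxels to average")
    return float(cc.cc[sel].mean())
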