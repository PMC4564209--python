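"""Correlation ratio eta(J_T | I) via a sorted-index, bin-partitioned reduction.

The correlation ratio (CR) between a reference image I and a transformed
moving image J_T measures how much of J_T's variance is explained by
conditioning on the intensity bin of I::

    eta(J_T | I) = 1 - (1 / (N * sigma^2)) * sum_i N_i * sigma_i^2

where sigma^2 and m are variance/mean of J_T over the overlap region Omega,
and sigma_i^2, m_i are variance/mean over the isointensity set Omega_i (the
overlap voxels whose reference intensity falls in histogram bin i).  eta is
1 for purely deterministic dependence and 0 for no functional dependence.

The production path mirrors the bin-partitioned reduction scheme: the
reference is binned once, its voxels are stably sorted by bin so every bin
occupies a contiguous slice of one index array, and per-bin partial
statistics (N_i, sum, sum of squares of J_T) are accumulated by traversing
bin slices in any grouping — the result is independent of the partitioning.
A naive direct-grouping oracle (:func:`correlation_ratio_direct`) provides
the independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import Volume

__all__ = [
    "BinnedReference",
    "SortedIntensityIndex",
    "BinStatistics",
    "CRResult",
    "CRError",
    "bin_reference",
    "build_sorted_index",
    "sample_transformed",
    "accumulate_bin_stats",
    "correlation_ratio",
    "correlation_ratio_direct",
]


class CRError(ValueError):
    """Empty overlap, zero variance, or inconsistent inputs."""


@dataclass
class BinnedReference:
    """Reference voxels mapped to uniform histogram bins.

    ``bin_of_voxel`` is -1 outside the mask; in-mask voxels carry a bin index
    in [0, n_bins).  ``degenerate`` flags a constant (single-bin) reference.
    """

    bin_of_voxel: np.ndarray
    n_bins: int
    bin_edges: np.ndarray
    mask: np.ndarray
    degenerate: bool = False


@dataclass
class SortedIntensityIndex:
    """Voxel indices stably sorted by bin, with per-bin slice marks.

    ``entries[bin_start[i]:bin_end[i]]`` are the linear voxel indices of bin
    i, in their original linear order (stable sort), so the concatenation of
    all bin slices is a permutation of the in-mask voxels.
    """

    entries: np.ndarray        # linear voxel indices, grouped by bin
    entry_bins: np.ndarray     # bin index of each entry (non-decreasing)
    bin_start: np.ndarray      # per-bin first position in `entries`
    bin_end: np.ndarray        # per-bin one-past-last position
    n_bins: int
    shape: tuple[int, int, int]


@dataclass
class BinStatistics:
    """Per-bin N_i, sum of J_T and sum of J_T^2 over overlap voxels."""

    count: np.ndarray
    sum: np.ndarray
    sum_sq: np.ndarray


@dataclass
class CRResult:
    eta: float
    n_overlap: int
    sigma_sq: float
    per_bin: BinStatistics


def bin_reference(volume: Volume, n_bins: int, mask: np.ndarray | None = None) -> BinnedReference:
    """Assign every in-mask reference voxel to one of ``n_bins`` uniform bins.

    Edges span the in-mask min-max; the maximum intensity falls in the last
    bin.  A constant reference puts every voxel in bin 0 and sets the
    ``degenerate`` flag.
    """
    if n_bins < 2:
        raise CRError(f"n_bins must be >= 2, got {n_bins}")
    data = volume.data
    if mask is None:
        mask = np.ones(data.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape:
            raise CRError("mask shape mismatch")
    if not mask.any():
        raise CRError("empty mask")
    vals = data[mask]
    lo, hi = float(vals.min()), float(vals.max())
    bins = np.full(data.shape, -1, dtype=np.int64)
    if hi == lo:
        bins[mask] = 0
        edges = np.linspace(lo, lo + 1.0, n_bins + 1)
        return BinnedReference(bins, n_bins, edges, mask, degenerate=True)
    edges = np.linspace(lo, hi, n_bins + 1)
    b = np.floor((data[mask] - lo) / (hi - lo) * n_bins).astype(np.int64)
    np.clip(b, 0, n_bins - 1, out=b)  # max intensity into the last bin
    bins[mask] = b
    return BinnedReference(bins, n_bins, edges, mask)


def build_sorted_index(binned: BinnedReference) -> SortedIntensityIndex:
    """Stably sort in-mask voxels by bin and mark each bin's slice.

    The stage-level preprocessing step: built once per resolution stage and
    reused for every candidate transform evaluated at that stage.
    """
    build_sorted_index.counter += 1
    lin = np.flatnonzero(binned.mask.ravel())
    b = binned.bin_of_voxel.ravel()[lin]
    order = np.argsort(b, kind="stable")
    entries = lin[order]
    entry_bins = b[order]
    counts = np.bincount(entry_bins, minlength=binned.n_bins)
    bin_end = np.cumsum(counts)
    bin_start = bin_end - counts
    return SortedIntensityIndex(
        entries=entries,
        entry_bins=entry_bins,
        bin_start=bin_start,
        bin_end=bin_end,
        n_bins=binned.n_bins,
        shape=binned.bin_of_voxel.shape,
    )


build_sorted_index.counter = 0  # instrumentation: builds since import


def sample_transformed(moving: Volume, transform, reference: Volume):
    """Sample J_T = J o T on the reference grid.

    Each reference voxel center is mapped through ``transform`` (a
    world-coordinate affine) into the moving image; ``overlap`` is True where
    the mapped point lies within the moving volume's interpolatable extent.
    Returns ``(values, overlap)`` grids on the reference shape; values outside
    the overlap are edge-clamped samples and must be masked by callers.
    """
    matrix = np.asarray(getattr(transform, "matrix", transform), dtype=np.float64)
    if abs(np.linalg.det(matrix[:3, :3])) < 1e-12:
        raise CRError("singular transform")
    pts = reference.voxel_centers_world()
    mapped = matrix[:3, :3] @ pts + matrix[:3, 3:4]
    idx = moving.world_to_index(mapped)
    dims = np.asarray(moving.shape, dtype=np.float64)
    overlap = np.all((idx >= 0.0) & (idx <= (dims - 1.0)[:, None]), axis=0)
    vals = ndimage.map_coordinates(moving.data, idx, order=1, mode="nearest")
    return vals.reshape(reference.shape), overlap.reshape(reference.shape)


def accumulate_bin_stats(
    index: SortedIntensityIndex,
    values: np.ndarray,
    overlap: np.ndarray,
    n_partitions: int = 1,
) -> BinStatistics:
    """Accumulate per-bin N_i, sum J_T, sum J_T^2 over overlap voxels.

    Bins are processed in ``n_partitions`` contiguous groups and partial
    results merged — the serial equivalent of the per-bin parallel blocks —
    so the output is independent of the partitioning.
    """
    if values.shape != index.shape or overlap.shape != index.shape:
        raise CRError("values/overlap shape does not match the index grid")
    if n_partitions < 1:
        raise CRError("n_partitions must be >= 1")
    v = values.ravel()
    ov = overlap.ravel()
    count = np.zeros(index.n_bins, dtype=np.int64)
    s = np.zeros(index.n_bins, dtype=np.float64)
    ss = np.zeros(index.n_bins, dtype=np.float64)
    for group in np.array_split(np.arange(index.n_bins), min(n_partitions, index.n_bins)):
        if group.size == 0:
            continue
        lo = index.bin_start[group[0]]
        hi = index.bin_end[group[-1]]
        vox = index.entries[lo:hi]
        bins = index.entry_bins[lo:hi] - group[0]
        keep = ov[vox]
        vox, bins = vox[keep], bins[keep]
        if vox.size == 0:
            continue
        vals = v[vox]
        nb = group.size
        count[group] += np.bincount(bins, minlength=nb)
        s[group] += np.bincount(bins, weights=vals, minlength=nb)
        ss[group] += np.bincount(bins, weights=vals * vals, minlength=nb)
    return BinStatistics(count=count, sum=s, sum_sq=ss)


def correlation_ratio(
    stats: BinStatistics,
    values: np.ndarray | None = None,
    overlap: np.ndarray | None = None,
) -> CRResult:
    """Merge per-bin statistics into eta(J_T | I).

    The global mean/variance are the merged bin sums (every overlap voxel
    lies in exactly one bin, so this equals the direct Omega statistics).
    Bins with N_i <= 1 have zero conditional variance and contribute nothing.
    """
    n = int(stats.count.sum())
    if n == 0:
        raise CRError("empty overlap")
    total = float(stats.sum.sum())
    total_sq = float(stats.sum_sq.sum())
    m = total / n
    sigma_sq = total_sq / n - m * m
    if sigma_sq <= 0.0:
        raise CRError("zero variance of J_T over the overlap")
    occupied = stats.count > 1
    within = float(
        np.sum(stats.sum_sq[occupied] - stats.sum[occupied] ** 2 / stats.count[occupied])
    )
    eta = 1.0 - within / (n * sigma_sq)
    # guard float round-off at the boundaries; eta is in [0, 1] analytically
    eta = min(max(eta, 0.0), 1.0)
    return CRResult(eta=eta, n_overlap=n, sigma_sq=sigma_sq, per_bin=stats)


def correlation_ratio_direct(
    binned: BinnedReference, values: np.ndarray, overlap: np.ndarray
) -> float:
    """Naive direct-grouping oracle for eta, bypassing the sorted index."""
    sel = binned.mask & np.asarray(overlap, dtype=bool)
    if not sel.any():
        raise CRError("empty overlap")
    v = np.asarray(values, dtype=np.float64)[sel]
    b = binned.bin_of_voxel[sel]
    n = v.size
    sigma_sq = float(v.var())
    if sigma_sq <= 0.0:
        raise CRError("zero variance of J_T over the overlap")
    within = 0.0
    for i in np.unique(b):
        vi = v[b == i]
        if vi.size > 1:
            within += vi.size * float(vi.var())
    eta = 1.0 - within / (n * sigma_sq)
    return min(max(eta, 0.0), 1.0)
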