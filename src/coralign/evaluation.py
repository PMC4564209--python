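"""Registration assessment: mean absolute difference and Jaccard overlap.

MAD is the mean voxelwise |a - b| between two co-registered scalar volumes.
The Jaccard index of a structure is |A n B| / |A u B| over its voxel sets in
two label volumes; background (label 0) is excluded from the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .affine_register import AffineTransform
from .symmetric_cc_register import DisplacementField
from .volume_io import LabelVolume, Volume

__all__ = ["OverlapReport", "mad", "jaccard", "transform_labels"]


@dataclass
class OverlapReport:
    """Per-label Jaccard values plus intersection/union voxel counts."""

    per_label: dict[int, float]
    intersections: dict[int, int]
    unions: dict[int, int]

    @property
    def mean_jaccard(self) -> float:
        """Mean over foreground labels present in either volume."""
        if not self.per_label:
            return float("nan")
        return float(np.mean(list(self.per_label.values())))


def mad(a: Volume, b: Volume, mask: np.ndarray | None = None) -> float:
    """Mean absolute voxelwise difference over the mask (default: all)."""
    da = np.asarray(getattr(a, "data", a), dtype=np.float64)
    db = np.asarray(getattr(b, "data", b), dtype=np.float64)
    if da.shape != db.shape:
        raise ValueError(f"shape mismatch {da.shape} vs {db.shape}")
    diff = np.abs(da - db)
    if mask is None:
        return float(diff.mean())
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return float(diff[mask].mean())


def jaccard(a: LabelVolume, b: LabelVolume) -> OverlapReport:
    """Per-label intersection-over-union of two co-dimensioned label maps.

    Labels absent from both volumes are omitted; a label present in exactly
    one volume scores 0.
    """
    la, lb = a.data, b.data
    if la.shape != lb.shape:
        raise ValueError(f"shape mismatch {la.shape} vs {lb.shape}")
    labels = np.union1d(np.unique(la), np.unique(lb))
    labels = labels[labels > 0]
    per_label, inters, unions = {}, {}, {}
    for lab in labels:
        in_a = la == lab
        in_b = lb == lab
        inter = int(np.count_nonzero(in_a & in_b))
        union = int(np.count_nonzero(in_a | in_b))
        per_label[int(lab)] = inter / union if union else 0.0
        inters[int(lab)] = inter
        unions[int(lab)] = union
    return OverlapReport(per_label=per_label, intersections=inters, unions=unions)


def transform_labels(labels: LabelVolume, transform, reference: Volume) -> LabelVolume:
    """Carry a label map through an affine or displacement field.

    Nearest-neighbor resampling onto the reference grid; voxels mapping
    outside the source extent become background (0).
    """
    if isinstance(transform, AffineTransform):
        pts = reference.voxel_centers_world()
        mapped = transform.apply(pts)
        idx = (mapped - labels.origin[:, None]) / labels.spacing[:, None]
    elif isinstance(transform, DisplacementField):
        if transform.shape != reference.shape:
            raise ValueError("displacement field must live on the reference grid")
        grid = np.indices(reference.shape, dtype=np.float64)
        idx = (grid + np.moveaxis(transform.vectors, -1, 0)
               / labels.spacing[:, None, None, None]).reshape(3, -1)
    else:
        raise TypeError(f"unsupported transform type {type(transform)!r}")
    out = ndimage.map_coordinates(
        labels.data, idx, order=0, mode="constant", cval=0
    )
    return LabelVolume(
        out.reshape(reference.shape).astype(np.int32),
        reference.spacing.copy(),
        reference.origin.copy(),
    )
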