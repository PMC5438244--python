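"""Lung segmentation and lung-volume bookkeeping.

The analysis mask follows the threshold rule: voxels strictly below −250 HU
inside the lung outlines.  When no outline is supplied, exterior air is
removed by discarding low-HU connected components that touch the volume
boundary, and small residual specks are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ImageVolume
from .errors import ContractError, SegmentationError

__all__ = [
    "LungMask",
    "segment_lung",
    "lung_volume",
    "union_mask",
    "percent_volume_difference",
    "DEFAULT_THRESHOLD_HU",
]

DEFAULT_THRESHOLD_HU = -250.0

#: components smaller than this fraction of the largest are treated as specks
_MIN_COMPONENT_FRACTION = 0.05


@dataclass
class LungMask:
    """Binary mask on an :class:`~ctperf.core.ImageVolume` grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[str, str, str] = ("right-left", "ventral-dorsal", "cranial-caudal")

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ContractError(f"mask must be 3-D, got shape {self.mask.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.orientation = tuple(self.orientation)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    def same_grid(self, other) -> bool:
        return (
            self.shape == (other.shape if isinstance(other.shape, tuple) else tuple(other.shape))
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    @staticmethod
    def from_volume(volume: ImageVolume, mask: np.ndarray) -> "LungMask":
        return LungMask(mask, volume.spacing, volume.origin, volume.orientation)

    def as_volume(self) -> ImageVolume:
        return ImageVolume(
            self.mask.astype(float), self.spacing, self.origin, self.orientation
        )


def segment_lung(
    volume: ImageVolume,
    threshold: float = DEFAULT_THRESHOLD_HU,
    outline: LungMask | None = None,
    cleanup: bool = False,
) -> LungMask:
    """Threshold-based lung segmentation.

    ``mask = (HU < threshold)`` — strictly less-than — restricted to ``outline``
    when given; otherwise exterior air (low-HU components touching the volume
    boundary) is removed and the remaining large components are kept.

    With ``cleanup`` a one-voxel binary closing and hole fill are applied after
    thresholding (off by default; the threshold rule is the contract).
    """
    low = volume.voxels < threshold
    if outline is not None:
        if outline.shape != volume.shape:
            raise ContractError("outline mask grid does not match the volume")
        body = low & outline.mask
    else:
        labels, n = ndimage.label(low)
        if n == 0:
            raise SegmentationError(
                f"no voxels below {threshold} HU (volume range "
                f"[{volume.voxels.min():.0f}, {volume.voxels.max():.0f}] HU)"
            )
        border = np.zeros(volume.shape, dtype=bool)
        border[[0, -1], :, :] = True
        border[:, [0, -1], :] = True
        border[:, :, [0, -1]] = True
        exterior = np.unique(labels[border & low])
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        counts[exterior] = 0
        if counts.max() == 0:
            raise SegmentationError(
                "all low-HU regions touch the volume boundary; no interior lung found"
            )
        keep = np.flatnonzero(counts >= _MIN_COMPONENT_FRACTION * counts.max())
        body = np.isin(labels, keep)
    if cleanup:
        body = ndimage.binary_closing(body, iterations=1)
        body = ndimage.binary_fill_holes(body)
    if not body.any():
        raise SegmentationError("segmentation produced an empty mask")
    return LungMask.from_volume(volume, body)


def lung_volume(mask: LungMask) -> float:
    """Volume of the set voxels in cm³."""
    return mask.count * float(np.prod(mask.spacing)) / 1000.0


def union_mask(a: LungMask, b: LungMask) -> LungMask:
    """Voxelwise logical OR (the merged fixed/moving lung mask for DIR)."""
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing) or not np.allclose(a.origin, b.origin):
        raise ContractError("union_mask requires identical grids")
    return LungMask(a.mask | b.mask, a.spacing, a.origin, a.orientation)


def percent_volume_difference(v_ref: float, v_new: float) -> float:
    """100 × (v_new − v_ref) / v_ref."""
    if v_ref <= 0:
        raise ContractError(f"reference volume must be positive, got {v_ref}")
    return 100.0 * (v_new - v_ref) / v_ref
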