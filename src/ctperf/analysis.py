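"""Perfusion statistics: heterogeneity, gravitational gradient, group tests.

* Overall heterogeneity is the coefficient of variation (CoV = SD/mean) of HU
  enhancement over the lung mask.  CoV scales out multiplicative changes but
  not additive shifts — meaningful here because HU enhancement has a physical
  zero.
* The gravitationally directed gradient splits the masked lung into equal-
  thickness coronal slabs along the ventral-dorsal axis, regresses the slab
  mean enhancements on the relative slab-centre distance (k+0.5)/n, and tests
  the slope against zero with the regression t-test (n−2 df).
* Group comparisons use the classical pooled-variance two-sample two-tailed
  t-test by default (Welch available).

SD convention: sample SD (n−1) by default; population SD via ``ddof=0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ContractError
from .hu_correction import PerfusionMap

__all__ = [
    "GradientReport",
    "GroupComparison",
    "coefficient_of_variation",
    "group_mean",
    "two_sample_t_test",
    "coronal_roi_means",
    "gradient_regression",
    "overall_enhancement",
]


@dataclass
class GradientReport:
    """Ventral-to-dorsal gradient of regional perfusion.

    ``roi_means`` are ordered ventral → dorsal; ``distances`` are the relative
    slab centres (k+0.5)/n in [0, 1]; regression fields are filled in by
    :func:`gradient_regression`.
    """

    roi_means: np.ndarray
    distances: np.ndarray
    roi_counts: np.ndarray
    slope: float | None = None       # HU per unit relative distance
    intercept: float | None = None   # HU
    r_squared: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        self.roi_means = np.asarray(self.roi_means, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        self.roi_counts = np.asarray(self.roi_counts, dtype=int)
        if not (len(self.roi_means) == len(self.distances) == len(self.roi_counts)):
            raise ContractError("ROI means, distances and counts must have equal length")
        if np.any(np.diff(self.distances) <= 0):
            raise ContractError("ROIs must be ordered ventral to dorsal")


@dataclass
class GroupComparison:
    """Two-group comparison of per-subject statistics."""

    group_a: np.ndarray
    group_b: np.ndarray
    t_statistic: float
    p_value: float
    variant: str = "pooled"
    mean_a: float = field(init=False)
    mean_b: float = field(init=False)
    #: set when the groups are perfectly separated with zero pooled variance
    exact_separation: bool = False

    def __post_init__(self) -> None:
        self.group_a = np.asarray(self.group_a, dtype=float)
        self.group_b = np.asarray(self.group_b, dtype=float)
        self.mean_a = float(self.group_a.mean())
        self.mean_b = float(self.group_b.mean())


def coefficient_of_variation(perfusion: PerfusionMap, ddof: int = 1) -> float:
    """SD/mean of masked HU enhancement (sample SD by default)."""
    vals = perfusion.values()
    if len(vals) == 0:
        raise ContractError("perfusion mask is empty")
    mean = vals.mean()
    if mean == 0:
        raise ContractError("mean enhancement is zero; CoV undefined")
    return float(vals.std(ddof=ddof) / mean)


def group_mean(values) -> float:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ContractError("cannot average an empty group")
    return float(values.mean())


def two_sample_t_test(a, b, variant: str = "pooled") -> GroupComparison:
    """Two-sample two-tailed t-test (pooled variance by default).

    Degenerate inputs: identical constant groups give t = 0, p = 1; perfectly
    separated constant groups give the p → 0 limit, flagged via
    ``exact_separation``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ContractError("each group needs at least two observations")
    if variant not in ("pooled", "welch"):
        raise ContractError(f"unknown t-test variant {variant!r}")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return GroupComparison(a, b, t_statistic=0.0, p_value=1.0, variant=variant)
        return GroupComparison(
            a, b, t_statistic=float("inf") if a.mean() > b.mean() else float("-inf"),
            p_value=0.0, variant=variant, exact_separation=True,
        )
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return GroupComparison(a, b, t_statistic=float(res.statistic),
                           p_value=float(res.pvalue), variant=variant)


def _vd_axis(orientation) -> tuple[int, bool]:
    for i, label in enumerate(orientation):
        if label == "ventral-dorsal":
            return i, True
        if label == "dorsal-ventral":
            return i, False
    raise ContractError(f"orientation {orientation!r} has no ventral-dorsal axis")


def coronal_roi_means(perfusion: PerfusionMap, n_rois: int = 5) -> GradientReport:
    """Mean enhancement in equal-thickness coronal slabs, ventral to dorsal.

    The masked lung's extent along the ventral-dorsal axis (between the
    extreme masked voxel centres) is divided into ``n_rois`` contiguous slabs
    of equal geometric thickness; voxels are assigned by centre position.
    """
    if n_rois < 1:
        raise ContractError("need at least one ROI")
    enh = perfusion.enhancement
    axis, ascending = _vd_axis(enh.orientation)
    mask = perfusion.mask.mask
    idx_along = np.nonzero(mask)[axis]
    coords = enh.origin[axis] + enh.spacing[axis] * idx_along
    if not ascending:
        coords = -coords  # measure from the ventral side
    lo, hi = float(coords.min()), float(coords.max())
    if hi == lo:
        slab = np.zeros(len(coords), dtype=int)
    else:
        slab = np.minimum(
            ((coords - lo) / (hi - lo) * n_rois).astype(int), n_rois - 1
        )
    vals = perfusion.values()
    means = np.empty(n_rois)
    counts = np.empty(n_rois, dtype=int)
    for k in range(n_rois):
        sel = slab == k
        counts[k] = int(sel.sum())
        if counts[k] == 0:
            raise ContractError(f"coronal slab {k} contains no masked voxels")
        means[k] = float(vals[sel].mean())
    distances = (np.arange(n_rois) + 0.5) / n_rois
    return GradientReport(roi_means=means, distances=distances, roi_counts=counts)


def gradient_regression(report: GradientReport) -> GradientReport:
    """OLS of slab means on relative distance; two-tailed slope t-test."""
    x = report.distances
    y = report.roi_means
    if len(x) < 3:
        raise ContractError("gradient regression needs at least three ROIs")
    if np.ptp(x) == 0:
        raise ContractError("degenerate ROI distances (all equal)")
    if np.ptp(y) == 0:  # flat profile: zero slope, no explained variance
        report.slope = 0.0
        report.intercept = float(y[0])
        report.r_squared = 0.0
        report.p_value = 1.0
        return report
    res = stats.linregress(x, y)
    report.slope = float(res.slope)
    report.intercept = float(res.intercept)
    report.r_squared = float(res.rvalue**2)
    report.p_value = float(res.pvalue)
    return report


def overall_enhancement(perfusion: PerfusionMap, ddof: int = 1) -> tuple[float, float]:
    """Mean and SD (HU) of masked enhancement."""
    vals = perfusion.values()
    if len(vals) == 0:
        raise ContractError("perfusion mask is empty")
    return float(vals.mean()), float(vals.std(ddof=ddof))
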