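"""Voxel-wise HU-vs-lung-volume modelling and subtraction perfusion.

Parenchymal HU falls as the lung inflates (more air per voxel), so a raw
postcontrast-minus-precontrast subtraction confounds contrast enhancement
with any inflation difference between the two end-inspiratory breath-holds.
The correction models HU at each voxel as a straight line in total lung
volume, fitted to the three aligned precontrast scans, then replaces the
precontrast end-inspiratory HU with the line evaluated at the postcontrast
lung volume (interpolation or — logged — extrapolation).  Perfusion is the
HU difference between the deformed postcontrast scan and this corrected
precontrast scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import BSplineTransform, DisplacementField, ImageVolume, compose_fields, warp
from .errors import ContractError
from .segmentation import LungMask

__all__ = [
    "VoxelLinearModel",
    "PerfusionMap",
    "build_aligned_stack",
    "fit_hu_volume_model",
    "correct_hu",
    "compute_perfusion",
    "negative_fraction",
]

logger = logging.getLogger(__name__)


@dataclass
class VoxelLinearModel:
    """Per-voxel straight line HU(V) = intercept + slope × V.

    ``slope`` is in HU/cm³ (negative in parenchyma: deeper inflation, lower
    HU); arrays live on the end-inspiratory reference grid and are defined
    only inside ``mask`` — querying outside the mask is flagged, never
    silently zero.
    """

    slope: np.ndarray
    intercept: np.ndarray
    mask: LungMask
    #: (min, max) of the total lung volumes used in the fit, cm³
    volume_range: tuple[float, float]

    def __post_init__(self) -> None:
        self.slope = np.asarray(self.slope, dtype=float)
        self.intercept = np.asarray(self.intercept, dtype=float)
        if self.slope.shape != self.intercept.shape or self.slope.shape != self.mask.shape:
            raise ContractError("slope, intercept and mask must share one grid")
        inside_s = self.slope[self.mask.mask]
        inside_i = self.intercept[self.mask.mask]
        if not (np.all(np.isfinite(inside_s)) and np.all(np.isfinite(inside_i))):
            raise ContractError("model has non-finite values inside its mask")

    def predict(self, volume_cm3: float) -> np.ndarray:
        """Fitted HU at a lung volume; NaN outside the fit mask."""
        out = np.full(self.slope.shape, np.nan)
        m = self.mask.mask
        out[m] = self.intercept[m] + self.slope[m] * float(volume_cm3)
        return out


@dataclass
class PerfusionMap:
    """Per-voxel HU enhancement with negative-value bookkeeping."""

    enhancement: ImageVolume
    mask: LungMask
    negative_count: int = field(init=False)
    negative_fraction: float = field(init=False)
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        if self.enhancement.shape != self.mask.shape:
            raise ContractError("enhancement and mask must share one grid")
        if self.mask.count == 0:
            raise ContractError("perfusion mask is empty")
        vals = self.values()
        self.negative_count = int((vals < 0).sum())
        self.negative_fraction = self.negative_count / len(vals)
        self.mean = float(vals.mean())
        self.sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    def values(self) -> np.ndarray:
        return self.enhancement.voxels[self.mask.mask]


def build_aligned_stack(
    end_exp: ImageVolume,
    mid_ins: ImageVolume,
    end_ins: ImageVolume,
    t_exp_to_mid: DisplacementField | BSplineTransform,
    t_mid_to_ins: DisplacementField | BSplineTransform,
) -> tuple[ImageVolume, ImageVolume, ImageVolume]:
    """Bring the three precontrast scans onto the end-inspiratory grid.

    ``t_exp_to_mid`` maps midinspiration (fixed) to end-expiration (moving);
    ``t_mid_to_ins`` maps end-inspiration (fixed) to midinspiration (moving) —
    the registration chain run with end-inspiration as the final fixed image.
    The end-expiratory scan is resampled *once* through the composed field
    (not twice through the chain), and the end-inspiratory scan passes through
    untouched.
    """
    geom = ImageVolume(np.zeros(end_ins.shape), end_ins.spacing, end_ins.origin,
                       end_ins.orientation)
    f_mid_to_ins = _as_field(t_mid_to_ins, geom)
    f_exp_to_mid = _as_field(t_exp_to_mid, geom)
    if f_mid_to_ins.shape != end_ins.shape:
        raise ContractError("t_mid_to_ins does not match the end-inspiratory grid")
    composed = compose_fields(outer=f_exp_to_mid, inner=f_mid_to_ins)
    exp_aligned = warp(end_exp, composed, interpolation="linear")
    mid_aligned = warp(mid_ins, f_mid_to_ins, interpolation="linear")
    return exp_aligned, mid_aligned, end_ins


def _as_field(t, geom: ImageVolume) -> DisplacementField:
    if isinstance(t, BSplineTransform):
        return t.rasterize(geom)
    if isinstance(t, DisplacementField):
        return t
    raise ContractError(f"unsupported transform type {type(t)!r}")


def fit_hu_volume_model(
    aligned: tuple[ImageVolume, ImageVolume, ImageVolume],
    volumes_cm3: tuple[float, float, float],
    mask: LungMask,
) -> VoxelLinearModel:
    """Ordinary least squares of HU against total lung volume, per voxel.

    With exactly three observations the fit has one residual degree of
    freedom; collinear inputs are interpolated exactly.
    """
    volumes = np.asarray(volumes_cm3, dtype=float)
    if len(volumes) != 3 or len(aligned) != 3:
        raise ContractError("exactly three aligned scans and volumes are required")
    if len(np.unique(volumes)) != 3:
        raise ContractError(f"lung volumes must be distinct, got {volumes.tolist()}")
    for vol in aligned:
        if vol.shape != mask.shape:
            raise ContractError("aligned scans and mask must share one grid")
    m = mask.mask
    hu = np.stack([vol.voxels[m] for vol in aligned])  # (3, n)
    vc = volumes - volumes.mean()
    slope_in = (vc[:, None] * (hu - hu.mean(axis=0))).sum(axis=0) / (vc @ vc)
    intercept_in = hu.mean(axis=0) - slope_in * volumes.mean()
    slope = np.full(mask.shape, np.nan)
    intercept = np.full(mask.shape, np.nan)
    slope[m] = slope_in
    intercept[m] = intercept_in
    return VoxelLinearModel(
        slope=slope,
        intercept=intercept,
        mask=mask,
        volume_range=(float(volumes.min()), float(volumes.max())),
    )


def correct_hu(
    end_ins_pre: ImageVolume,
    model: VoxelLinearModel,
    target_volume_cm3: float,
) -> ImageVolume:
    """Replace precontrast end-inspiratory HU with the fitted HU at the
    postcontrast lung volume.

    Inside the model mask the output is ``intercept + slope × target_volume``
    (note: at the end-inspiratory fit volume this is the OLS *fitted* value,
    not the raw HU); outside the mask the original HU passes through.  A
    target volume outside the fitted range extrapolates the line, unclamped,
    with a warning logged.
    """
    if target_volume_cm3 <= 0:
        raise ContractError(f"target volume must be positive, got {target_volume_cm3}")
    if end_ins_pre.shape != model.mask.shape:
        raise ContractError("model grid does not match the end-inspiratory scan")
    lo, hi = model.volume_range
    if not lo <= target_volume_cm3 <= hi:
        span = hi - lo
        excess = max(lo - target_volume_cm3, target_volume_cm3 - hi)
        logger.warning(
            "HU correction extrapolating: target volume %.1f cm³ lies %.1f%% "
            "outside the fitted range [%.1f, %.1f] cm³",
            target_volume_cm3, 100.0 * excess / span, lo, hi,
        )
    out = end_ins_pre.voxels.copy()
    m = model.mask.mask
    out[m] = model.intercept[m] + model.slope[m] * float(target_volume_cm3)
    return end_ins_pre.with_voxels(out)


def compute_perfusion(
    corrected_pre: ImageVolume,
    deformed_post: ImageVolume,
    mask: LungMask,
) -> PerfusionMap:
    """Enhancement = deformed postcontrast − corrected precontrast, in-mask."""
    if corrected_pre.shape != deformed_post.shape or corrected_pre.shape != mask.shape:
        raise ContractError("perfusion inputs must share one grid")
    enh = deformed_post.voxels - corrected_pre.voxels
    vol = ImageVolume(enh, corrected_pre.spacing, corrected_pre.origin,
                      corrected_pre.orientation)
    return PerfusionMap(enhancement=vol, mask=mask)


def negative_fraction(perfusion: PerfusionMap) -> float:
    """Fraction of masked voxels with strictly negative enhancement."""
    if perfusion.mask.count == 0:
        raise ContractError("perfusion mask is empty")
    return perfusion.negative_fraction
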