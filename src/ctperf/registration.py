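"""Multi-resolution B-spline deformable registration.

The deformation is a cubic B-spline free-form deformation optimized coarse to
fine: each resolution level smooths/down-samples the images (Gaussian
pyramid), refines the control grid, and minimizes

    total cost = similarity + bending_weight × bending energy

with L-BFGS-B and fully analytic gradients.  The similarity is either negated
normalized cross correlation (NCC) or negated mutual information (MI, linear
partial-volume weighting inside the optimizer), evaluated only on the
(dilated) lung mask.  The bending energy — the mean summed squared second
spatial derivative of the displacement — is computed exactly from the
B-spline basis, so affine displacements cost exactly zero.

Everything is deterministic: no stochastic sampling is used, so a given
(fixed, moving, mask, config) reproduces the same transform bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .core import BSplineTransform, DisplacementField, ImageVolume, gaussian_pyramid
from .errors import ContractError, OptimizationError
from .segmentation import LungMask

__all__ = [
    "RegistrationConfig",
    "CostBreakdown",
    "similarity_ncc",
    "similarity_mi",
    "bending_energy",
    "register",
    "jacobian_determinant",
    "count_singularities",
]

#: (axis_i, axis_j, multiplicity) for the bending-energy Hessian terms
_BEND_TERMS = [(0, 0, 1.0), (1, 1, 1.0), (2, 2, 1.0),
               (0, 1, 2.0), (0, 2, 2.0), (1, 2, 2.0)]


@dataclass(frozen=True)
class RegistrationConfig:
    """Multi-resolution schedule and cost settings.

    Defaults are scaled for ~64³ desk-scale volumes; the canonical clinical
    schedule for full-size thoracic CT is five levels with down-sampling
    factors 16/8/4/2/1 and grid spacings 80/40/20/10/5 mm, with a bending
    weight of 0.05.
    """

    factors: tuple[int, ...] = (4, 2, 1, 1)
    grid_spacing_mm: tuple[float, ...] = (112.0, 56.0, 28.0, 14.0)
    similarity: str = "ncc"  # "ncc" | "mi"
    bending_weight: float = 0.05
    mi_bins: int = 48
    #: optimizer iteration budget, one int for all levels or one per level
    iterations: int | tuple[int, ...] = (300, 200, 150, 100)
    tolerance: float = 1e-8
    mask_dilation_voxels: int = 2
    #: Gaussian smoothing (voxels) of the finest pyramid level; damps noise
    #: and keeps the interpolated intensity model consistent with its sampled
    #: gradient
    finest_sigma: float = 1.0
    #: per-level trust region on control coefficients, as a fraction of the
    #: level's grid spacing: the coarsest level may move each coefficient by
    #: capture_fraction × spacing (capture range), finer levels refine the
    #: upsampled initialisation by refine_fraction × spacing.  Keeping the
    #: refinement below ~0.4 × spacing also keeps the per-level update
    #: diffeomorphic (classic B-spline folding bound).
    capture_fraction: float = 0.75
    refine_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.factors) != len(self.grid_spacing_mm):
            raise ContractError("factors and grid_spacing_mm must have equal length")
        if any(a < b for a, b in zip(self.factors, self.factors[1:])):
            raise ContractError(f"factors must be nonincreasing, got {self.factors}")
        if self.bending_weight < 0:
            raise ContractError("bending weight must be nonnegative")
        if self.similarity not in ("ncc", "mi"):
            raise ContractError(f"unknown similarity {self.similarity!r}")
        if self.mi_bins < 2:
            raise ContractError("mi_bins must be at least 2")

    @property
    def levels(self) -> int:
        return len(self.factors)

    def iterations_for_level(self, level: int) -> int:
        if isinstance(self.iterations, int):
            return self.iterations
        return int(self.iterations[level])


@dataclass
class CostBreakdown:
    """Similarity + weighted bending-energy decomposition of the final cost."""

    similarity: float
    bending: float
    weight: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = self.similarity + self.weight * self.bending


# ---------------------------------------------------------------------------
# similarity metrics (public, value-only form)
# ---------------------------------------------------------------------------

def _masked_pair(fixed: ImageVolume, moving_warped: ImageVolume, mask: LungMask):
    if fixed.shape != moving_warped.shape or fixed.shape != mask.shape:
        raise ContractError("similarity requires fixed, moving and mask on one grid")
    if mask.count == 0:
        raise ContractError("similarity mask is empty")
    return fixed.voxels[mask.mask], moving_warped.voxels[mask.mask]


def similarity_ncc(fixed: ImageVolume, moving_warped: ImageVolume, mask: LungMask) -> float:
    """Negated normalized cross correlation over the mask (lower is better)."""
    f, m = _masked_pair(fixed, moving_warped, mask)
    fc = f - f.mean()
    mc = m - m.mean()
    sf = float(fc @ fc)
    sm = float(mc @ mc)
    if sf == 0.0 or sm == 0.0:
        raise ContractError("zero intensity variance within the mask; NCC undefined")
    return float(-(fc @ mc) / np.sqrt(sf * sm))


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def similarity_mi(
    fixed: ImageVolume,
    moving_warped: ImageVolume,
    mask: LungMask,
    bins: int = 32,
    weighting: str = "hard",
) -> float:
    """Negated mutual information (nats) of the masked joint histogram.

    ``weighting="hard"`` bins both images by nearest bin (so MI of an image
    with itself is exactly its marginal entropy); ``"pv"`` distributes the
    moving intensity linearly over the two neighbouring bins, matching the
    histogram the optimizer differentiates.
    """
    if bins < 2:
        raise ContractError("bins must be at least 2")
    f, m = _masked_pair(fixed, moving_warped, mask)
    if weighting == "hard":
        hist, _, _ = np.histogram2d(f, m, bins=bins)
    elif weighting == "pv":
        hist = _pv_histogram(f, m, bins)[0]
    else:
        raise ContractError(f"unknown weighting {weighting!r}")
    n = hist.sum()
    pj = hist / n
    mi = _entropy(pj.sum(axis=1)) + _entropy(pj.sum(axis=0)) - _entropy(pj.ravel())
    return float(-mi)


def _bin_edges(values: np.ndarray, bins: int) -> tuple[float, float]:
    lo = float(values.min())
    hi = float(values.max())
    if hi <= lo:
        hi = lo + 1.0
    return lo, (hi - lo) / bins


def _pv_histogram(f: np.ndarray, m: np.ndarray, bins: int,
                  f_edges=None, m_edges=None):
    """Joint histogram: hard binning for f, linear partial volume for m."""
    flo, fw = _bin_edges(f, bins) if f_edges is None else f_edges
    mlo, mw = _bin_edges(m, bins) if m_edges is None else m_edges
    fk = np.clip(((f - flo) / fw).astype(int), 0, bins - 1)
    t = np.clip((m - mlo) / mw, 0.0, bins - 1 - 1e-9)
    l0 = t.astype(int)
    frac = t - l0
    hist = np.zeros((bins, bins))
    np.add.at(hist, (fk, l0), 1.0 - frac)
    np.add.at(hist, (fk, l0 + 1), frac)
    return hist, fk, l0, frac, (flo, fw), (mlo, mw)


# ---------------------------------------------------------------------------
# bending energy (exact on the B-spline basis)
# ---------------------------------------------------------------------------

def _bending_mats(transform: BSplineTransform, geom: ImageVolume):
    """Per-axis basis matrices of derivative order 0/1/2 at the grid coords."""
    coords = geom.world_coords()
    return [
        [transform.basis_matrix(coords[axis], axis, derivative=d) for d in range(3)]
        for axis in range(3)
    ]


def _tensor_apply(mats: list[np.ndarray], coeffs: np.ndarray) -> np.ndarray:
    out = coeffs
    for axis, m in enumerate(mats):
        out = np.moveaxis(np.tensordot(m, out, axes=(1, axis)), 0, axis)
    return out


def bending_energy(transform: BSplineTransform, geometry: ImageVolume | None = None) -> float:
    """Mean summed squared second derivative of the displacement.

    The integrand Σ_c Σ_ij λ_ij (∂²d_c/∂u_i∂u_j)² (λ=1 diagonal, 2 mixed) is
    evaluated exactly from the B-spline basis at every voxel of the domain and
    averaged per sample point, so any affine displacement scores exactly 0.

    Spatial coordinates u are measured in native voxel lengths of the
    transform's fixed-image domain (u_i = x_i / spacing_i), making the value
    dimensionally mm² per voxel⁴ and the penalty weight transferable across
    image resolutions and pyramid levels.
    """
    geom = transform.domain if geometry is None else geometry
    mats = _bending_mats(transform, geom)
    energy, _ = _bending_energy_grad(
        transform.coefficients, mats, transform.domain.spacing, want_grad=False
    )
    return energy


def _bending_energy_grad(coeffs: np.ndarray, mats, voxel_mm, want_grad: bool = True):
    n_samples = mats[0][0].shape[0] * mats[1][0].shape[0] * mats[2][0].shape[0]
    energy = 0.0
    grad = np.zeros_like(coeffs) if want_grad else None
    for ai, aj, mult in _BEND_TERMS:
        orders = [0, 0, 0]
        orders[ai] += 1
        orders[aj] += 1
        # derivatives per voxel length, not per mm: ∂²d/∂u_i∂u_j = h_i h_j ∂²d/∂x_i∂x_j
        weight = mult * (voxel_mm[ai] * voxel_mm[aj]) ** 2
        term_mats = [mats[axis][orders[axis]] for axis in range(3)]
        d2 = _tensor_apply(term_mats, coeffs)
        energy += weight * float((d2**2).sum()) / n_samples
        if want_grad:
            mats_t = [m.T for m in term_mats]
            grad += (2.0 * weight / n_samples) * _tensor_apply(mats_t, d2)
    return energy, grad


# ---------------------------------------------------------------------------
# cost function with analytic gradient
# ---------------------------------------------------------------------------

class _LevelProblem:
    """Cost + gradient for one resolution level."""

    def __init__(self, transform: BSplineTransform, fixed: ImageVolume,
                 moving: ImageVolume, mask: np.ndarray, config: RegistrationConfig):
        self.transform = transform
        self.fixed = fixed
        self.moving = moving
        self.mask_idx = np.nonzero(mask)
        if self.mask_idx[0].size == 0:
            raise ContractError("registration mask is empty at a pyramid level")
        self.config = config
        self.spacing = np.asarray(fixed.spacing)
        self.mats = _bending_mats(transform, fixed)
        self.value_mats = [self.mats[a][0] for a in range(3)]
        self.f = fixed.voxels[self.mask_idx]
        self.moving_grads = np.gradient(moving.voxels, *fixed.spacing)
        self.base_idx = np.stack([idx.astype(float) for idx in self.mask_idx])
        if config.similarity == "mi":
            self.f_edges = _bin_edges(self.f, config.mi_bins)
            mv = moving.voxels[self.mask_idx]
            lo, w = _bin_edges(mv, config.mi_bins)
            # pad the moving range: warped intensities can drift outside
            pad = 2.0 * w
            self.m_edges = (lo - pad, w + 2 * pad / config.mi_bins)

    def _similarity(self, m: np.ndarray):
        if self.config.similarity == "ncc":
            return self._ncc(m)
        return self._mi(m)

    def _ncc(self, m: np.ndarray):
        f = self.f
        fc = f - f.mean()
        mc = m - m.mean()
        sf = float(fc @ fc)
        sm = float(mc @ mc)
        if sf == 0.0:
            raise ContractError("zero fixed-image variance within the mask; NCC undefined")
        if sm < 1e-12:
            return 0.0, np.zeros_like(m)
        denom = np.sqrt(sf * sm)
        ncc = float(fc @ mc) / denom
        grad = -(fc / denom - ncc * mc / sm)
        return -ncc, grad

    def _mi(self, m: np.ndarray):
        bins = self.config.mi_bins
        hist, fk, l0, frac, _, (mlo, mw) = _pv_histogram(
            self.f, m, bins, f_edges=self.f_edges, m_edges=self.m_edges
        )
        n = float(len(m))
        pj = hist / n
        mi = _entropy(pj.sum(axis=1)) + _entropy(pj.sum(axis=0)) - _entropy(pj.ravel())
        # d(-MI)/dm via the log-ratio table T[k,l] = log H[k,l] - log H_l[l]
        safe = np.log(np.maximum(hist, 1e-300))
        safe_l = np.log(np.maximum(hist.sum(axis=0), 1e-300))
        table = safe - safe_l[None, :]
        dmi = (table[fk, l0 + 1] - table[fk, l0]) / (n * mw)
        return -mi, -dmi

    def cost(self, params: np.ndarray):
        coeffs = params.reshape(self.transform.coefficients.shape)
        disp = _tensor_apply(self.value_mats, coeffs)
        coords = self.base_idx + np.stack(
            [disp[self.mask_idx + (v,)] / self.spacing[v] for v in range(3)]
        )
        # clamped sampling: out-of-grid positions read the edge value, keeping
        # the cost continuous (a constant fill is discontinuous exactly at the
        # grid edge and offers the optimizer a spurious uniform region)
        m = ndimage.map_coordinates(self.moving.voxels, coords, order=1, mode="nearest")
        sim, dsim_dm = self._similarity(m)
        bend, bend_grad = _bending_energy_grad(
            coeffs, self.mats, self.transform.domain.spacing
        )
        total = sim + self.config.bending_weight * bend
        if not np.isfinite(total):
            raise OptimizationError(
                f"non-finite cost (similarity={sim}, bending={bend})"
            )
        vox_grad = np.zeros(disp.shape)
        for v in range(3):
            gm = ndimage.map_coordinates(
                self.moving_grads[v], coords, order=1, mode="nearest"
            )
            vox_grad[self.mask_idx + (v,)] = dsim_dm * gm
        mats_t = [m_.T for m_ in self.value_mats]
        grad = _tensor_apply(mats_t, vox_grad)
        grad += self.config.bending_weight * bend_grad
        return total, grad.ravel(), sim, bend

    def fun(self, params: np.ndarray):
        total, grad, _, _ = self.cost(params)
        return total, grad


def _fit_coefficients(transform: BSplineTransform, target: DisplacementField) -> np.ndarray:
    """Least-squares fit of control coefficients to a dense target field.

    The rasterization operator is a tensor product of per-axis basis matrices,
    so the least-squares solution is the per-axis pseudo-inverse applied
    sequentially.
    """
    geom = target.geometry_like()
    mats = [transform.basis_matrix(geom.world_coords()[a], a) for a in range(3)]
    pinvs = [np.linalg.pinv(m) for m in mats]
    return _tensor_apply(pinvs, target.vectors)


def register(
    fixed: ImageVolume,
    moving: ImageVolume,
    mask: LungMask,
    config: RegistrationConfig | None = None,
) -> tuple[BSplineTransform, CostBreakdown, list[dict]]:
    """Coarse-to-fine B-spline registration of ``moving`` onto ``fixed``.

    ``mask`` is the merged fixed/moving lung mask on the fixed grid; the
    similarity is sampled only inside the mask dilated by
    ``config.mask_dilation_voxels``.  Returns the transform (fixed->moving),
    the final full-resolution cost breakdown, and a per-level log with start
    and end costs (end ≤ start at every level).
    """
    config = config or RegistrationConfig()
    if not fixed.same_grid(moving):
        raise ContractError("fixed and moving must share one grid")
    if mask.shape != fixed.shape:
        raise ContractError("mask must live on the fixed grid")
    if mask.count == 0:
        raise ContractError("registration mask is empty")
    mask_arr = mask.mask
    if config.mask_dilation_voxels > 0:
        mask_arr = ndimage.binary_dilation(mask_arr, iterations=config.mask_dilation_voxels)

    factors = list(config.factors)
    fixed_pyr = gaussian_pyramid(fixed, factors, finest_sigma=config.finest_sigma)
    moving_pyr = gaussian_pyramid(moving, factors, finest_sigma=config.finest_sigma)

    transform: BSplineTransform | None = None
    log: list[dict] = []
    for level, factor in enumerate(factors):
        fx = fixed_pyr[level]
        mv = moving_pyr[level]
        mask_level = mask_arr[::factor, ::factor, ::factor]
        spacing = (config.grid_spacing_mm[level],) * 3
        new_transform = BSplineTransform.identity(fixed, spacing)
        if transform is not None:
            new_transform.coefficients = _fit_coefficients(
                new_transform, transform.rasterize(fx)
            )
        transform = new_transform

        problem = _LevelProblem(transform, fx, mv, mask_level, config)
        x0 = transform.coefficients.ravel().copy()
        maxiter = config.iterations_for_level(level)
        f0, _, sim0, bend0 = problem.cost(x0)
        if maxiter > 0:
            trace = [f0]
            cache: dict = {}

            def fun(params, _problem=problem, _cache=cache):
                total, grad = _problem.fun(params)
                _cache["last"] = total
                return total, grad

            def callback(xk, _cache=cache, _trace=trace):
                _trace.append(_cache["last"])

            frac = config.capture_fraction if level == 0 else config.refine_fraction
            cap = frac * config.grid_spacing_mm[level]
            result = optimize.minimize(
                fun,
                x0,
                jac=True,
                method="L-BFGS-B",
                callback=callback,
                bounds=optimize.Bounds(x0 - cap, x0 + cap),
                options={"maxiter": maxiter, "ftol": config.tolerance, "gtol": 1e-12,
                         "maxcor": 12},
            )
            transform.coefficients = result.x.reshape(transform.coefficients.shape)
            f_end, _, sim_end, bend_end = problem.cost(result.x)
            if f_end > f0:  # L-BFGS-B never accepts an increase; keep the start
                transform.coefficients = x0.reshape(transform.coefficients.shape)
                f_end, sim_end, bend_end = f0, sim0, bend0
            n_iter = int(result.nit)
        else:
            f_end, sim_end, bend_end = f0, sim0, bend0
            trace = [f0]
            n_iter = 0
        log.append(
            {
                "level": level,
                "factor": factor,
                "grid_spacing_mm": config.grid_spacing_mm[level],
                "iterations": n_iter,
                "cost_start": float(f0),
                "cost_end": float(f_end),
                "similarity_end": float(sim_end),
                "bending_end": float(bend_end),
                "trace": [float(t) for t in trace],
            }
        )

    final = _LevelProblem(transform, fixed_pyr[-1], moving_pyr[-1],
                          mask_arr[:: factors[-1], :: factors[-1], :: factors[-1]], config)
    _, _, sim, bend = final.cost(transform.coefficients.ravel())
    breakdown = CostBreakdown(similarity=float(sim), bending=float(bend),
                              weight=config.bending_weight)
    return transform, breakdown, log


# ---------------------------------------------------------------------------
# displacement-field diagnostics
# ---------------------------------------------------------------------------

def jacobian_determinant(displacement: DisplacementField) -> ImageVolume:
    """Per-voxel determinant of I + ∇d (local volume ratio of the mapping).

    Central differences in the interior, one-sided at the boundary.
    """
    v = displacement.vectors
    sp = displacement.spacing
    J = np.empty(v.shape[:3] + (3, 3))
    for i in range(3):
        for j in range(3):
            J[..., i, j] = np.gradient(v[..., i], sp[j], axis=j)
    J[..., 0, 0] += 1.0
    J[..., 1, 1] += 1.0
    J[..., 2, 2] += 1.0
    det = (
        J[..., 0, 0] * (J[..., 1, 1] * J[..., 2, 2] - J[..., 1, 2] * J[..., 2, 1])
        - J[..., 0, 1] * (J[..., 1, 0] * J[..., 2, 2] - J[..., 1, 2] * J[..., 2, 0])
        + J[..., 0, 2] * (J[..., 1, 0] * J[..., 2, 1] - J[..., 1, 1] * J[..., 2, 0])
    )
    return ImageVolume(det, displacement.spacing, displacement.origin, displacement.orientation)


def count_singularities(jacobian: ImageVolume, mask: LungMask) -> int:
    """Number of masked voxels where the Jacobian determinant is ≤ 0."""
    if jacobian.shape != mask.shape:
        raise ContractError("jacobian and mask must share one grid")
    return int((jacobian.voxels[mask.mask] <= 0.0).sum())
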