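"""Volume and transform data model shared by all pipeline stages.

Conventions
-----------
* World coordinates are in millimetres; voxel indices are 0-based.
* ``ImageVolume`` grids are axis-aligned: array axis ``i`` runs along one
  anatomical direction, named by ``orientation[i]`` (e.g. ``"ventral-dorsal"``
  means increasing index moves from the ventral to the dorsal side).
* Displacement fields map *fixed*-frame points to *moving*-frame points, in mm:
  the moving image sample for fixed-frame position ``x`` is taken at
  ``x + d(x)``.
* Samples requested outside a volume take a fill value (default −1000 HU, air),
  so subtraction degrades gracefully near the lung borders.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import ContractError, FormatError, ParseError

__all__ = [
    "ImageVolume",
    "DisplacementField",
    "BSplineTransform",
    "read_volume",
    "write_volume",
    "read_field",
    "write_field",
    "warp",
    "gaussian_pyramid",
    "compose_fields",
]

#: anatomical direction label -> unit vector in ITK LPS world axes
_LPS = {
    "right-left": (1.0, 0.0, 0.0),
    "left-right": (-1.0, 0.0, 0.0),
    "ventral-dorsal": (0.0, 1.0, 0.0),   # anterior -> posterior
    "dorsal-ventral": (0.0, -1.0, 0.0),
    "cranial-caudal": (0.0, 0.0, -1.0),  # superior -> inferior
    "caudal-cranial": (0.0, 0.0, 1.0),
}

DEFAULT_ORIENTATION = ("right-left", "ventral-dorsal", "cranial-caudal")

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_orientation(orientation: tuple[str, str, str]) -> tuple[str, str, str]:
    orientation = tuple(orientation)
    if len(orientation) != 3 or any(o not in _LPS for o in orientation):
        raise ContractError(f"unknown orientation labels: {orientation!r}")
    axes = {tuple(np.abs(_LPS[o])) for o in orientation}
    if len(axes) != 3:
        raise ContractError(
            f"orientation must be a signed permutation of the anatomical axes, got {orientation!r}"
        )
    return orientation


@dataclass
class ImageVolume:
    """A 3-D scalar grid (HU) with physical geometry.

    Attributes
    ----------
    voxels : (n0, n1, n2) float array of HU values.
    spacing : per-axis voxel size in mm (strictly positive).
    origin : world position (mm) of voxel (0, 0, 0).
    orientation : anatomical direction of each array axis.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[str, str, str] = DEFAULT_ORIENTATION

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ContractError(f"voxels must be 3-D, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ContractError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.orientation = _check_orientation(self.orientation)
        if not np.all(np.isfinite(self.voxels)):
            raise ContractError("voxels contain non-finite values")

    # -- geometry helpers ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ImageVolume | DisplacementField", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and self.orientation == other.orientation
        )

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1-D world coordinates (mm) of voxel centres."""
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i]) for i in range(3)
        )

    def world_grid(self) -> np.ndarray:
        """(n0, n1, n2, 3) array of voxel-centre world positions."""
        c0, c1, c2 = self.world_coords()
        g = np.empty(self.shape + (3,), dtype=float)
        g[..., 0] = c0[:, None, None]
        g[..., 1] = c1[None, :, None]
        g[..., 2] = c2[None, None, :]
        return g

    def index_from_world(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for world points (..., 3)."""
        points = np.asarray(points, dtype=float)
        return (points - np.asarray(self.origin)) / np.asarray(self.spacing)

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        return replace(self, voxels=voxels)


@dataclass
class DisplacementField:
    """Dense per-voxel displacement (mm), fixed frame -> moving frame."""

    vectors: np.ndarray  # (n0, n1, n2, 3)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[str, str, str] = DEFAULT_ORIENTATION

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ContractError(f"vectors must have shape (n0,n1,n2,3), got {self.vectors.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ContractError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.orientation = _check_orientation(self.orientation)
        if not np.all(np.isfinite(self.vectors)):
            raise ContractError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    def geometry_like(self) -> ImageVolume:
        """An empty ImageVolume sharing this field's grid (geometry carrier)."""
        return ImageVolume(
            np.zeros(self.shape), self.spacing, self.origin, self.orientation
        )

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated displacement (mm) at world points (..., 3)."""
        points = np.asarray(points, dtype=float)
        idx = (points - np.asarray(self.origin)) / np.asarray(self.spacing)
        flat = idx.reshape(-1, 3).T
        out = np.empty((points.size // 3, 3))
        for v in range(3):
            out[:, v] = ndimage.map_coordinates(
                self.vectors[..., v], flat, order=1, mode="nearest"
            )
        return out.reshape(points.shape)

    @staticmethod
    def zero_like(volume: ImageVolume) -> "DisplacementField":
        return DisplacementField(
            np.zeros(volume.shape + (3,)), volume.spacing, volume.origin, volume.orientation
        )


# ---------------------------------------------------------------------------
# Cubic B-spline free-form deformation
# ---------------------------------------------------------------------------

def _bspline_weights(t: np.ndarray, derivative: int = 0) -> np.ndarray:
    """Weights of the 4 cubic B-spline basis functions at fractional offset t.

    Returns shape t.shape + (4,) for control points floor(t)-1 .. floor(t)+2.
    ``derivative`` selects the 0th, 1st or 2nd derivative of the basis with
    respect to t (per unit of control spacing).
    """
    t = np.asarray(t, dtype=float)
    if derivative == 0:
        w0 = (1 - t) ** 3 / 6.0
        w1 = (3 * t**3 - 6 * t**2 + 4) / 6.0
        w2 = (-3 * t**3 + 3 * t**2 + 3 * t + 1) / 6.0
        w3 = t**3 / 6.0
    elif derivative == 1:
        w0 = -((1 - t) ** 2) / 2.0
        w1 = (9 * t**2 - 12 * t) / 6.0
        w2 = (-9 * t**2 + 6 * t + 3) / 6.0
        w3 = t**2 / 2.0
    elif derivative == 2:
        w0 = 1 - t
        w1 = 3 * t - 2
        w2 = -3 * t + 1
        w3 = t
    else:  # pragma: no cover
        raise ValueError(derivative)
    return np.stack([w0, w1, w2, w3], axis=-1)


@dataclass
class BSplineTransform:
    """Cubic B-spline free-form deformation over an image domain.

    ``coefficients`` has shape (nc0, nc1, nc2, 3): mm displacement coefficients
    on a control grid with spacing ``grid_spacing`` (mm) and origin
    ``grid_origin`` (mm, world position of control point (0,0,0)).  The
    transform maps a fixed-frame world point x to x + d(x).
    """

    grid_spacing: tuple[float, float, float]
    grid_origin: tuple[float, float, float]
    coefficients: np.ndarray
    domain: ImageVolume = field(repr=False)  # geometry carrier for the fixed grid

    def __post_init__(self) -> None:
        self.grid_spacing = tuple(float(s) for s in self.grid_spacing)
        if any(s <= 0 for s in self.grid_spacing):
            raise ContractError(f"grid spacing must be positive, got {self.grid_spacing}")
        self.grid_origin = tuple(float(o) for o in self.grid_origin)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 4 or self.coefficients.shape[-1] != 3:
            raise ContractError("coefficients must have shape (nc0,nc1,nc2,3)")

    # -- construction -------------------------------------------------------
    @staticmethod
    def identity(domain: ImageVolume, grid_spacing: tuple[float, float, float]) -> "BSplineTransform":
        """Zero-displacement transform whose control grid covers ``domain``."""
        grid_spacing = tuple(float(s) for s in grid_spacing)
        shape = []
        origin = []
        for i in range(3):
            extent = domain.spacing[i] * (domain.shape[i] - 1)
            n_span = int(np.ceil(extent / grid_spacing[i])) + 1
            # one extra control point on each side for full cubic support
            shape.append(n_span + 2)
            origin.append(domain.origin[i] - grid_spacing[i])
        coeffs = np.zeros(tuple(shape) + (3,))
        return BSplineTransform(grid_spacing, tuple(origin), coeffs, domain)

    def basis_matrix(self, coords_mm: np.ndarray, axis: int, derivative: int = 0) -> np.ndarray:
        """Dense (npoints, ncontrol) basis matrix along one axis.

        ``coords_mm`` are world coordinates along ``axis``; derivatives are with
        respect to mm (chain rule through the control spacing applied).
        """
        h = self.grid_spacing[axis]
        n_ctrl = self.coefficients.shape[axis]
        t = (np.asarray(coords_mm, dtype=float) - self.grid_origin[axis]) / h
        base = np.floor(t).astype(int)
        frac = t - base
        w = _bspline_weights(frac, derivative) / h**derivative
        mat = np.zeros((t.size, n_ctrl))
        rows = np.arange(t.size)
        for k in range(4):
            col = np.clip(base + k - 1, 0, n_ctrl - 1)
            np.add.at(mat, (rows, col), w[:, k])
        return mat

    def _tensor_apply(self, mats: list[np.ndarray], coeffs: np.ndarray | None = None) -> np.ndarray:
        """Apply per-axis matrices to the coefficient tensor -> dense samples."""
        out = self.coefficients if coeffs is None else coeffs
        for axis, m in enumerate(mats):
            out = np.moveaxis(np.tensordot(m, out, axes=(1, axis)), 0, axis)
        return out

    def rasterize(self, geometry: ImageVolume | None = None) -> DisplacementField:
        """Evaluate the transform on an image grid -> dense DisplacementField."""
        geom = self.domain if geometry is None else geometry
        mats = [self.basis_matrix(geom.world_coords()[i], i) for i in range(3)]
        vec = self._tensor_apply(mats)
        return DisplacementField(vec, geom.spacing, geom.origin, geom.orientation)

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        """Exact B-spline displacement (mm) at arbitrary world points (..., 3)."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        n = pts.shape[0]
        out = np.zeros((n, 3))
        bases = []
        fracs = []
        for axis in range(3):
            h = self.grid_spacing[axis]
            t = (pts[:, axis] - self.grid_origin[axis]) / h
            b = np.floor(t).astype(int)
            bases.append(b)
            fracs.append(_bspline_weights(t - b))
        nc = self.coefficients.shape
        for k0 in range(4):
            i0 = np.clip(bases[0] + k0 - 1, 0, nc[0] - 1)
            w0 = fracs[0][:, k0]
            for k1 in range(4):
                i1 = np.clip(bases[1] + k1 - 1, 0, nc[1] - 1)
                w01 = w0 * fracs[1][:, k1]
                for k2 in range(4):
                    i2 = np.clip(bases[2] + k2 - 1, 0, nc[2] - 1)
                    out += (w01 * fracs[2][:, k2])[:, None] * self.coefficients[i0, i1, i2]
        return out.reshape(np.asarray(points, dtype=float).shape)


# ---------------------------------------------------------------------------
# File I/O (SimpleITK: NIfTI and MetaImage)
# ---------------------------------------------------------------------------

def _orientation_to_direction(orientation: tuple[str, str, str]) -> tuple[float, ...]:
    cols = [_LPS[o] for o in orientation]
    # ITK direction matrix: column j = world direction of image axis j
    return tuple(cols[j][r] for r in range(3) for j in range(3))


def _direction_to_orientation(direction: tuple[float, ...]) -> tuple[str, str, str]:
    d = np.asarray(direction, dtype=float).reshape(3, 3)
    labels = []
    for j in range(3):
        col = d[:, j]
        best = None
        for name, vec in _LPS.items():
            if np.allclose(col, vec, atol=1e-3):
                best = name
                break
        if best is None:
            raise ParseError(f"volume direction matrix is not axis-aligned: {direction}")
        labels.append(best)
    return _check_orientation(tuple(labels))


def _check_path_format(path: str | os.PathLike) -> str:
    p = str(path)
    if not any(p.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise FormatError(
            f"unsupported volume format for {p!r}; expected one of {_SUPPORTED_SUFFIXES}"
        )
    return p


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume."""
    p = _check_path_format(path)
    if not os.path.exists(p):
        raise FormatError(f"no such file: {p}")
    try:
        img = sitk.ReadImage(p)
    except Exception as exc:  # SimpleITK raises bare RuntimeError
        raise ParseError(f"could not read {p}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ParseError(f"{p} is not a 3-D volume")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x) in index order
    # SimpleITK index order is (x, y, z); transpose so array axis i == image axis i
    voxels = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(float)
    return ImageVolume(
        voxels,
        tuple(img.GetSpacing()),
        tuple(img.GetOrigin()),
        _direction_to_orientation(img.GetDirection()),
    )


def write_volume(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume; round-trips bit-exactly through :func:`read_volume`."""
    p = _check_path_format(path)
    parent = os.path.dirname(p) or "."
    if not os.path.isdir(parent):
        raise OSError(f"parent directory does not exist: {parent}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.voxels.transpose(2, 1, 0)))
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    img.SetDirection(_orientation_to_direction(volume.orientation))
    try:
        sitk.WriteImage(img, p)
    except Exception as exc:
        raise OSError(f"could not write {p}: {exc}") from exc


def write_field(fieldv: DisplacementField, path: str | os.PathLike) -> None:
    """Store a displacement field as a 3-component vector volume."""
    p = _check_path_format(path)
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(fieldv.vectors.transpose(2, 1, 0, 3)), isVector=True
    )
    img.SetSpacing(fieldv.spacing)
    img.SetOrigin(fieldv.origin)
    img.SetDirection(_orientation_to_direction(fieldv.orientation))
    sitk.WriteImage(img, p)


def read_field(path: str | os.PathLike) -> DisplacementField:
    p = _check_path_format(path)
    if not os.path.exists(p):
        raise FormatError(f"no such file: {p}")
    try:
        img = sitk.ReadImage(p)
    except Exception as exc:
        raise ParseError(f"could not read {p}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ParseError(f"{p} is not a 3-component vector volume")
    return DisplacementField(
        np.ascontiguousarray(arr.transpose(2, 1, 0, 3)).astype(float),
        tuple(img.GetSpacing()),
        tuple(img.GetOrigin()),
        _direction_to_orientation(img.GetDirection()),
    )


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def warp(
    moving: ImageVolume,
    displacement: DisplacementField,
    interpolation: str = "linear",
    fill_value: float = -1000.0,
) -> ImageVolume:
    """Resample ``moving`` through a fixed->moving displacement field.

    The output lives on the field's grid; voxel at fixed position x takes the
    interpolated moving value at x + d(x).  Samples outside the moving volume
    take ``fill_value`` (air by default).
    """
    if moving.orientation != displacement.orientation:
        raise ContractError("warp requires moving and field to share orientation")
    if interpolation not in ("linear", "nearest"):
        raise ContractError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "linear" else 0
    geom = displacement.geometry_like()
    target = geom.world_grid() + displacement.vectors
    idx = moving.index_from_world(target)
    out = ndimage.map_coordinates(
        moving.voxels, idx.reshape(-1, 3).T, order=order, mode="constant", cval=fill_value
    ).reshape(displacement.shape)
    return ImageVolume(out, displacement.spacing, displacement.origin, displacement.orientation)


def gaussian_pyramid(
    volume: ImageVolume, factors: list[int], finest_sigma: float = 0.0
) -> list[ImageVolume]:
    """Gaussian down-sampling pyramid.

    Level k is the input smoothed with sigma = factors[k]/2 voxels per axis
    then subsampled by stride factors[k].  The factor-1 level is the original,
    optionally smoothed with ``finest_sigma`` voxels.  Spacing scales
    accordingly; the origin stays at voxel (0,0,0).
    """
    factors = [int(f) for f in factors]
    if any(f <= 0 for f in factors):
        raise ContractError(f"factors must be positive integers, got {factors}")
    if any(a < b for a, b in zip(factors, factors[1:])):
        raise ContractError(f"factors must be nonincreasing, got {factors}")
    if any(f > min(volume.shape) for f in factors):
        raise ContractError(f"factor exceeds volume extent {volume.shape}: {factors}")
    levels = []
    for f in factors:
        if f == 1:
            sm = volume.voxels
            if finest_sigma > 0:
                sm = ndimage.gaussian_filter(sm, sigma=finest_sigma, mode="nearest")
        else:
            sm = ndimage.gaussian_filter(volume.voxels, sigma=f / 2.0, mode="nearest")
        sub = sm[::f, ::f, ::f]
        levels.append(
            ImageVolume(sub, tuple(s * f for s in volume.spacing), volume.origin, volume.orientation)
        )
    return levels


def compose_fields(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Composition ``result(x) = inner(x) + outer(x + inner(x))``.

    Applies ``inner`` first (fixed frame -> intermediate), then the interpolated
    ``outer`` at the displaced position.  Composing with a zero field is the
    identity to well below 1e-9 mm.
    """
    if inner.orientation != outer.orientation:
        raise ContractError("compose_fields requires matching orientations")
    geom = inner.geometry_like()
    mid = geom.world_grid() + inner.vectors
    outer_at_mid = outer.displacement_at(mid)
    return DisplacementField(
        inner.vectors + outer_at_mid, inner.spacing, inner.origin, inner.orientation
    )
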