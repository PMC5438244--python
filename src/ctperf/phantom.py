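"""Synthetic four-scan breath-hold CT series with analytic ground truth.

The generator emulates the statistical structure the perfusion pipeline
assumes for a prone canine-like thorax:

* two ellipsoidal lung lobes inside a soft-tissue body, with a small vessel
  tree (+50 HU blood precontrast, strongly enhancing postcontrast);
* three precontrast inflation levels (end-expiration, midinspiration,
  end-inspiration) plus a postcontrast scan at a slightly different
  end-inspiratory level;
* parenchymal HU at a material point is *exactly linear* in total lung volume
  before noise (lower HU for deeper inflation), which is the modelling
  assumption the voxel-wise correction relies on;
* inflation deformations are anisotropic scalings about a point near the lung
  apex plus a bounded low-frequency sinusoidal perturbation, so the true
  mapping is smooth, invertible, and analytically evaluable everywhere;
* contrast enhancement is a ventral-to-dorsal linear gradient about a baseline
  ``e0``, optionally attenuated inside spherical perfusion defects.

All randomness is driven by the spec seed; identical specs give bit-identical
scans.  ``PhantomTruth`` exposes exact deformations, the exact per-voxel
HU-vs-volume line, the enhancement map, lung masks, and landmark sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .core import DEFAULT_ORIENTATION, DisplacementField, ImageVolume
from .errors import ContractError, SpecError
from .segmentation import LungMask
from .validation import LandmarkSet

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_series",
    "sample_landmarks",
    "expected_mean_enhancement",
    "expected_slab_gradient",
    "SCAN_NAMES",
]

SCAN_NAMES = ("end_exp_pre", "mid_ins_pre", "end_ins_pre", "end_ins_post")

_AIR_HU = -1000.0
_SOFT_TISSUE_HU = 50.0


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic subject.

    Volume targets default to the normal-group mean lung volumes of the
    reference canine cohort (1356 / 1865 / 2067 cm³ for the three precontrast
    levels, 2072 cm³ postcontrast).  Enhancement defaults give a ~35 HU mean
    with a ventral-to-dorsal decrease, in the range observed on real subjects.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (3.5, 3.5, 3.5)
    orientation: tuple[str, str, str] = DEFAULT_ORIENTATION
    #: total lung volume targets (cm³) at end-expiration, midinspiration,
    #: end-inspiration; must be strictly increasing
    volumes_cm3: tuple[float, float, float] = (1356.0, 1865.0, 2067.0)
    post_volume_cm3: float = 2072.0
    #: end-inspiratory (reference) lobe semi-axes before volume normalisation
    lobe_semiaxes_mm: tuple[float, float, float] = (42.0, 62.0, 95.0)
    lobe_offset_mm: float = 47.0
    #: parenchymal tissue fraction at the reference inflation level
    tissue_fraction: float = 0.134
    #: dimensionless stiffness of the HU-vs-volume line (higher = steeper)
    hu_volume_stiffness: float = 3.3
    #: relative spatial variation of tissue fraction and stiffness
    #: (large-scale, ~120–180 mm wavelengths)
    tissue_variation: float = 0.10
    stiffness_variation: float = 0.20
    #: fine-scale parenchymal density texture (~36–62 mm wavelengths),
    #: relative tissue-fraction amplitude emulating sub-lobar vessel/septal
    #: structure (±17 HU at end-inspiration); gives registration realistic
    #: structure to lock onto
    texture_variation: float = 0.12
    #: vessel tree: radii (mm) of the per-lobe segments and HU values
    vessel_radii_mm: tuple[float, ...] = (3.5, 2.5, 2.5)
    vessel_hu: float = 50.0
    vessel_enhancement_hu: float = 300.0
    #: enhancement baseline (HU) — the lung-mean enhancement by construction
    e0: float = 35.0
    #: ventral-to-dorsal enhancement slope, HU per unit relative distance
    vd_slope: float = -24.0
    #: perfusion defects: (center_mm (3,), radius_mm, attenuation in [0, 1]);
    #: enhancement inside a defect is multiplied by the attenuation factor
    defects: tuple[tuple[tuple[float, float, float], float, float], ...] = ()
    #: Gaussian noise SD in HU, added independently per scan
    noise_sd: float = 5.0
    #: peak sinusoidal perturbation (mm) of the inflation chain deformations
    perturbation_mm: float = 3.0
    #: peak perturbation (mm) between the two end-inspiratory scans — the
    #: deformation amplitude seen by the perfusion registration
    residual_amplitude_mm: float = 3.0
    #: share of the volume change carried by the cranial-caudal axis
    #: (0.5 means sz = det^0.5, diaphragm-dominated)
    anisotropy: float = 0.5
    #: scaling centre (mm), near the lung apex
    scale_center_mm: tuple[float, float, float] = (0.0, 0.0, -80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        v = self.volumes_cm3
        if not (v[0] < v[1] < v[2]):
            raise SpecError(f"volumes must be strictly increasing, got {v}")
        if not 0.0 < self.tissue_fraction < 1.0:
            raise SpecError(f"tissue fraction must be in (0,1), got {self.tissue_fraction}")
        for _, radius, att in self.defects:
            if not 0.0 <= att <= 1.0:
                raise SpecError(f"defect attenuation must be in [0,1], got {att}")
            if radius <= 0:
                raise SpecError("defect radius must be positive")
        if self.noise_sd < 0:
            raise SpecError("noise SD must be nonnegative")

    # -- derived geometry ---------------------------------------------------
    @property
    def level_volumes(self) -> dict[str, float]:
        return {
            "end_exp_pre": self.volumes_cm3[0],
            "mid_ins_pre": self.volumes_cm3[1],
            "end_ins_pre": self.volumes_cm3[2],
            "end_ins_post": self.post_volume_cm3,
        }

    def reference_semiaxes(self) -> np.ndarray:
        """Lobe semi-axes (mm) rescaled so two lobes hit the end-insp target."""
        a, b, c = self.lobe_semiaxes_mm
        v_two = 2.0 * (4.0 / 3.0) * np.pi * a * b * c / 1000.0  # cm³
        k = (self.volumes_cm3[2] / v_two) ** (1.0 / 3.0)
        return np.array([a, b, c]) * k

    def grid_geometry(self) -> ImageVolume:
        """Geometry carrier centred on the world origin."""
        origin = tuple(
            -(self.shape[i] - 1) * self.spacing[i] / 2.0 for i in range(3)
        )
        return ImageVolume(np.zeros(self.shape), self.spacing, origin, self.orientation)


# ---------------------------------------------------------------------------
# smooth sinusoidal fields (deterministic in the seed)
# ---------------------------------------------------------------------------

class _SinusoidField:
    """Sum of low-frequency sinusoids, normalised to peak amplitude 1.

    Vector fields (``n_components=3``) use one phase per mode with the
    amplitude vector projected perpendicular to the wavevector, making each
    mode divergence-free — the perturbation then changes lung volume only at
    second order, keeping segmented volumes on their targets.
    """

    def __init__(self, rng: np.random.Generator, n_components: int, n_modes: int = 3,
                 wavelengths=(160.0, 190.0, 220.0)):
        self.n_components = n_components
        probe_n = max(13, int(np.ceil(4 * 224.0 / min(wavelengths))) | 1)
        self.dirs = []
        self.freqs = []
        self.phases = []
        self.amps = []
        for _ in range(n_modes):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            lam = wavelengths[int(rng.integers(len(wavelengths)))]
            self.dirs.append(d)
            self.freqs.append(2.0 * np.pi / lam)
            if n_components == 1:
                self.phases.append(rng.uniform(0, 2 * np.pi, size=1))
                self.amps.append(rng.uniform(0.5, 1.0, size=1))
            else:
                self.phases.append(rng.uniform(0, 2 * np.pi, size=1).repeat(3))
                a = rng.normal(size=3)
                a -= (a @ d) * d  # divergence-free: amplitude ⊥ wavevector
                self.amps.append(a / np.linalg.norm(a))
        # normalise peak magnitude over a coarse probe of the domain
        probe = np.stack(
            np.meshgrid(*[np.linspace(-112, 112, probe_n)] * 3, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        vals = self._raw(probe)
        peak = np.abs(vals).max() if n_components == 1 else np.linalg.norm(vals, axis=-1).max()
        self.scale = 1.0 / peak

    def _raw(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        out = np.zeros(pts.shape[:-1] + (self.n_components,))
        for d, f, ph, am in zip(self.dirs, self.freqs, self.phases, self.amps):
            arg = f * (pts @ d)
            out += am * np.sin(arg[..., None] + ph)
        return out

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        out = self._raw(pts) * self.scale
        return out[..., 0] if self.n_components == 1 else out


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class PhantomTruth:
    """Exact generator internals: deformations, HU model, masks, landmarks."""

    spec: PhantomSpec
    geometry: ImageVolume = dc_field(repr=False)
    #: per-scan affine scale factors (3,) about the scaling centre
    scales: dict[str, np.ndarray] = dc_field(repr=False, default_factory=dict)
    #: per-scan perturbation amplitude (mm)
    amplitudes: dict[str, float] = dc_field(repr=False, default_factory=dict)
    psi_chain: _SinusoidField | None = dc_field(repr=False, default=None)
    psi_post: _SinusoidField | None = dc_field(repr=False, default=None)
    rho: _SinusoidField | None = dc_field(repr=False, default=None)
    chi: _SinusoidField | None = dc_field(repr=False, default=None)
    tau: _SinusoidField | None = dc_field(repr=False, default=None)
    #: world-frame vessel segments [(p0, p1, radius), ...] in material coords
    vessels: list = dc_field(repr=False, default_factory=list)
    #: exact level volumes (cm³) the HU model was built with
    volumes: dict[str, float] = dc_field(default_factory=dict)
    #: fixed outward shift (mm) of the lung edge blend placing the −250 HU
    #: crossing on the geometric lung surface (calibrated at the mid level)
    edge_shift_mm: float = 0.0
    lung_masks: dict[str, LungMask] = dc_field(repr=False, default_factory=dict)
    parenchyma_masks: dict[str, LungMask] = dc_field(repr=False, default_factory=dict)
    enhancement: ImageVolume | None = dc_field(repr=False, default=None)
    slope: ImageVolume | None = dc_field(repr=False, default=None)
    intercept: ImageVolume | None = dc_field(repr=False, default=None)
    landmarks: LandmarkSet | None = None

    # -- deformations -------------------------------------------------------
    def _psi(self, scan: str):
        return self.psi_post if scan == "end_ins_post" else self.psi_chain

    def phi(self, u: np.ndarray, scan: str) -> np.ndarray:
        """Material coordinates -> world position in scan ``scan``."""
        u = np.asarray(u, dtype=float)
        c = np.asarray(self.spec.scale_center_mm)
        s = self.scales[scan]
        out = c + (u - c) * s
        amp = self.amplitudes[scan]
        if amp != 0.0:
            out = out + amp * self._psi(scan)(u)
        return out

    def phi_inv(self, x: np.ndarray, scan: str, tol: float = 1e-9, max_iter: int = 60) -> np.ndarray:
        """Invert :meth:`phi` by fixed-point iteration (the perturbation is a
        contraction by construction)."""
        x = np.asarray(x, dtype=float)
        c = np.asarray(self.spec.scale_center_mm)
        s = self.scales[scan]
        amp = self.amplitudes[scan]
        if amp == 0.0:
            return c + (x - c) / s
        psi = self._psi(scan)
        u = c + (x - c) / s
        for _ in range(max_iter):
            u_next = c + (x - c - amp * psi(u)) / s
            step = np.max(np.abs(u_next - u))
            u = u_next
            if step < tol:
                break
        return u

    def displacement_at(self, points: np.ndarray, fixed: str, moving: str) -> np.ndarray:
        """Exact fixed->moving displacement (mm) at fixed-frame world points."""
        u = self.phi_inv(points, fixed)
        return self.phi(u, moving) - np.asarray(points, dtype=float)

    def displacement_field(self, fixed: str, moving: str) -> DisplacementField:
        """Truth displacement field rasterised on the (shared) scan grid."""
        pts = self.geometry.world_grid()
        vec = self.displacement_at(pts.reshape(-1, 3), fixed, moving).reshape(pts.shape)
        g = self.geometry
        return DisplacementField(vec, g.spacing, g.origin, g.orientation)

    # -- material model -----------------------------------------------------
    def _lobe_centers(self) -> np.ndarray:
        off = self.spec.lobe_offset_mm
        return np.array([[-off, 0.0, 0.0], [off, 0.0, 0.0]])

    def in_lung(self, u: np.ndarray, margin: float = 1.0) -> np.ndarray:
        """Points inside either reference lobe (margin shrinks the radius)."""
        semi = self.spec.reference_semiaxes()
        u = np.asarray(u, dtype=float)
        r2 = None
        for center in self._lobe_centers():
            q = ((u - center) / semi) ** 2
            s = q.sum(axis=-1)
            r2 = s if r2 is None else np.minimum(r2, s)
        return r2 <= margin**2

    def vessel_distance(self, u: np.ndarray) -> np.ndarray:
        """Distance (mm) to the nearest vessel centreline minus its radius."""
        u = np.asarray(u, dtype=float)
        flat = u.reshape(-1, 3)
        best = np.full(flat.shape[0], np.inf)
        for p0, p1, radius in self.vessels:
            seg = p1 - p0
            L2 = float(seg @ seg)
            t = np.clip(((flat - p0) @ seg) / L2, 0.0, 1.0)
            d = np.linalg.norm(flat - (p0 + t[:, None] * seg), axis=1) - radius
            best = np.minimum(best, d)
        return best.reshape(u.shape[:-1])

    def hu_line(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-point (slope HU/cm³, intercept HU) of parenchymal HU vs volume."""
        spec = self.spec
        u = np.asarray(u, dtype=float)
        t_ref = spec.tissue_fraction * (
            1.0
            + spec.tissue_variation * self.rho(u)
            + spec.texture_variation * self.tau(u)
        )
        beta = spec.hu_volume_stiffness * (1.0 + spec.stiffness_variation * self.chi(u))
        v_ref = spec.volumes_cm3[2]
        hu_range = _SOFT_TISSUE_HU - _AIR_HU  # 1050 HU between air and tissue
        slope = -hu_range * t_ref * beta / v_ref
        hu_at_ref = _AIR_HU + hu_range * t_ref
        intercept = hu_at_ref - slope * v_ref
        return slope, intercept

    def parenchyma_hu(self, u: np.ndarray, volume_cm3: float) -> np.ndarray:
        slope, intercept = self.hu_line(u)
        return intercept + slope * volume_cm3

    def vd_relative_position(self, u: np.ndarray) -> np.ndarray:
        """Relative ventral-to-dorsal position of material points in [0, 1]."""
        semi = self.spec.reference_semiaxes()
        axis = _vd_axis(self.spec.orientation)
        b = semi[axis]
        coord = np.asarray(u, dtype=float)[..., axis]
        if self.spec.orientation[axis].startswith("dorsal"):
            coord = -coord
        return np.clip((coord + b) / (2.0 * b), 0.0, 1.0)

    def enhancement_at(self, u: np.ndarray) -> np.ndarray:
        """Parenchymal enhancement (HU) at material points."""
        spec = self.spec
        p = self.vd_relative_position(u)
        e = spec.e0 + spec.vd_slope * (p - 0.5)
        u = np.asarray(u, dtype=float)
        for center, radius, att in spec.defects:
            inside = np.linalg.norm(u - np.asarray(center), axis=-1) <= radius
            e = np.where(inside, e * att, e)
        return e

    def aligned_noiseless_hu(self) -> dict[str, ImageVolume]:
        """The three precontrast scans evaluated analytically on the
        end-inspiratory grid (perfect alignment, no interpolation, no noise).

        At parenchymal voxels the three values are exactly collinear in the
        level volumes stored in :attr:`volumes`.
        """
        g = self.geometry
        pts = g.world_grid().reshape(-1, 3)
        out = {}
        for scan in ("end_exp_pre", "mid_ins_pre", "end_ins_pre"):
            hu = _material_hu(self, pts, self.volumes[scan], enhanced=False)
            out[scan] = ImageVolume(hu.reshape(g.shape), g.spacing, g.origin, g.orientation)
        return out


def _vd_axis(orientation: tuple[str, str, str]) -> int:
    for i, label in enumerate(orientation):
        if label in ("ventral-dorsal", "dorsal-ventral"):
            return i
    raise ContractError(f"orientation {orientation!r} has no ventral-dorsal axis")


#: soft-tissue shell thickness added to each lobe semi-axis to form the body
_BODY_MARGIN_MM = np.array([12.0, 14.0, 12.0])

#: half-widths (mm) of the smoothstep edge blends — the material model is
#: band-limited so that point sampling on any scan grid is alias-free and
#: trilinear interpolation is consistent across grids
_W_LUNG = 2.5
_W_VESSEL = 2.0
_W_BODY = 3.0


def _smoothstep(t: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: 0 at t≤0, 1 at t≥1, C² in between."""
    t = np.clip(t, 0.0, 1.0)
    return t * t * t * (t * (6.0 * t - 15.0) + 10.0)


def _blend_inside(d: np.ndarray, width: float, shift: float = 0.0) -> np.ndarray:
    """1 well inside (d ≪ 0), 0 well outside, transition over ±width.

    The blend is compactly supported: it is *exactly* 1 for d ≤ shift − width,
    so interior voxels carry the pure material value.
    """
    return 1.0 - _smoothstep((np.asarray(d) - shift) / (2.0 * width) + 0.5)


def _ellipsoid_signed_distance(u: np.ndarray, centers: np.ndarray, semi: np.ndarray) -> np.ndarray:
    """Approximate signed distance (mm, <0 inside) to a union of ellipsoids.

    First-order estimate d ≈ (q − 1)/|∇q| from the normalised radius q."""
    u = np.asarray(u, dtype=float)
    best = None
    for center in centers:
        rel = u - center
        q = np.sqrt(((rel / semi) ** 2).sum(axis=-1))
        gn = np.sqrt(((rel / semi**2) ** 2).sum(axis=-1)) / np.maximum(q, 1e-9)
        d = (q - 1.0) / np.maximum(gn, 1e-9)
        best = d if best is None else np.minimum(best, d)
    return best


def _material_hu(truth: PhantomTruth, u: np.ndarray, volume_cm3: float, enhanced: bool) -> np.ndarray:
    """HU of the band-limited material model at points ``u`` for one level.

    Every blend weight depends on the material coordinate only, so each
    point's HU remains exactly affine in total lung volume."""
    spec = truth.spec
    u = np.asarray(u, dtype=float)
    centers = truth._lobe_centers()
    semi = spec.reference_semiaxes()
    d_lung = _ellipsoid_signed_distance(u, centers, semi)
    d_body = _ellipsoid_signed_distance(u, centers, semi + _BODY_MARGIN_MM)
    near = d_lung < 2.0 * _W_LUNG  # vessels only matter inside the lung
    s_ves = np.zeros(u.shape[:-1])
    if np.any(near):
        s_ves[near] = _blend_inside(truth.vessel_distance(u[near]), _W_VESSEL)

    paren = truth.parenchyma_hu(u, volume_cm3)
    vessel = np.full(u.shape[:-1], spec.vessel_hu)
    if enhanced:
        paren = paren + truth.enhancement_at(u)
        vessel += spec.vessel_enhancement_hu
    inner = (1.0 - s_ves) * paren + s_ves * vessel

    s_lung = _blend_inside(d_lung, _W_LUNG, truth.edge_shift_mm)
    s_body = _blend_inside(d_body, _W_BODY)
    outer = (1.0 - s_body) * _AIR_HU + s_body * _SOFT_TISSUE_HU
    return (1.0 - s_lung) * outer + s_lung * inner


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _build_truth(spec: PhantomSpec) -> PhantomTruth:
    geom = spec.grid_geometry()
    semi = spec.reference_semiaxes()
    body_extent = np.array(
        [spec.lobe_offset_mm, 0.0, 0.0]
    ) + semi + _BODY_MARGIN_MM
    half_domain = np.array(
        [(spec.shape[i] - 1) * spec.spacing[i] / 2.0 for i in range(3)]
    )
    v_post = spec.post_volume_cm3
    det_max = max(1.0, v_post / spec.volumes_cm3[2])
    if np.any(body_extent * det_max ** (1 / 3) >= half_domain):
        raise SpecError(
            f"phantom body (semi-axes {body_extent}) does not fit inside the "
            f"grid (half-extent {half_domain}); enlarge the grid or shrink the lungs"
        )

    truth = PhantomTruth(spec=spec, geometry=geom)

    v_ref = spec.volumes_cm3[2]
    w = spec.anisotropy
    for scan, vol in spec.level_volumes.items():
        det = vol / v_ref
        sz = det**w
        sxy = det ** ((1.0 - w) / 2.0)
        truth.scales[scan] = np.array([sxy, sxy, sz])
        truth.volumes[scan] = float(vol)

    # amplitudes: zero at the reference level, growing with inflation distance
    v_exp = spec.volumes_cm3[0]
    for scan in ("end_exp_pre", "mid_ins_pre", "end_ins_pre"):
        frac = (v_ref - truth.volumes[scan]) / (v_ref - v_exp)
        truth.amplitudes[scan] = spec.perturbation_mm * frac
    truth.amplitudes["end_ins_post"] = spec.residual_amplitude_mm

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 17]))
    truth.psi_chain = _SinusoidField(rng, n_components=3)
    truth.psi_post = _SinusoidField(rng, n_components=3)
    truth.rho = _SinusoidField(rng, n_components=1, wavelengths=(120.0, 150.0, 180.0))
    truth.chi = _SinusoidField(rng, n_components=1, wavelengths=(120.0, 150.0, 180.0))
    truth.tau = _SinusoidField(rng, n_components=1, n_modes=6,
                               wavelengths=(36.0, 48.0, 62.0))

    # pin the −250 HU segmentation crossing to the geometric lung surface:
    # the blend runs from soft tissue (+50) to the mean parenchymal HU, so the
    # crossing fraction depends on inflation; calibrate once at the mid level
    v_mid = spec.volumes_cm3[1]
    hu_mean = _AIR_HU + (_SOFT_TISSUE_HU - _AIR_HU) * spec.tissue_fraction * (
        1.0 + spec.hu_volume_stiffness * (v_ref - v_mid) / v_ref
    )
    s_star = (_SOFT_TISSUE_HU - (-250.0)) / (_SOFT_TISSUE_HU - hu_mean)
    lo, hi = 0.0, 1.0
    for _ in range(60):  # invert the smoothstep by bisection
        mid = 0.5 * (lo + hi)
        if _smoothstep(np.array(mid)) < 1.0 - s_star:
            lo = mid
        else:
            hi = mid
    truth.edge_shift_mm = 2.0 * _W_LUNG * (0.5 - 0.5 * (lo + hi))

    # vessel tree: three segments per lobe, rooted near the hilum
    a, b, c = semi
    for side in (-1.0, 1.0):
        center = np.array([side * spec.lobe_offset_mm, 0.0, 0.0])
        entry = center + np.array([-side * 0.35 * a, 0.0, -0.35 * c])
        tips = [
            center + np.array([side * 0.15 * a, 0.0, 0.55 * c]),
            center + np.array([side * 0.45 * a, 0.45 * b, 0.30 * c]),
            center + np.array([side * 0.40 * a, -0.40 * b, -0.45 * c]),
        ]
        for tip, radius in zip(tips, spec.vessel_radii_mm):
            truth.vessels.append((entry, tip, float(radius)))
    return truth


def generate_series(spec: PhantomSpec) -> tuple[dict[str, ImageVolume], PhantomTruth]:
    """Generate the four scans and their ground truth.

    Returns ``(scans, truth)`` where ``scans`` maps the four scan names to
    :class:`~ctperf.core.ImageVolume` instances on a common grid.
    """
    truth = _build_truth(spec)
    geom = truth.geometry
    pts = geom.world_grid().reshape(-1, 3)

    scans: dict[str, ImageVolume] = {}
    for idx, scan in enumerate(SCAN_NAMES):
        u = truth.phi_inv(pts, scan)
        hu = _material_hu(truth, u, truth.volumes[scan], enhanced=(scan == "end_ins_post"))
        if spec.noise_sd > 0:
            noise_rng = np.random.default_rng(
                np.random.SeedSequence([int(spec.seed), 101 + idx])
            )
            hu = hu + noise_rng.normal(0.0, spec.noise_sd, size=hu.shape)
        scans[scan] = ImageVolume(
            hu.reshape(geom.shape), geom.spacing, geom.origin, geom.orientation
        )
        in_lung = truth.in_lung(u).reshape(geom.shape)
        # pure parenchyma: strictly inside every edge blend with one further
        # voxel of clearance, so the voxel HU *and its whole trilinear
        # interpolation stencil* carry the unblended linear-in-volume value
        margin = max(spec.spacing)
        d_lung = _ellipsoid_signed_distance(
            u, truth._lobe_centers(), spec.reference_semiaxes()
        ).reshape(geom.shape)
        paren = (
            (d_lung <= truth.edge_shift_mm - _W_LUNG - margin)
            & (truth.vessel_distance(u).reshape(geom.shape) >= _W_VESSEL + margin)
        )
        truth.lung_masks[scan] = LungMask(in_lung, geom.spacing, geom.origin, geom.orientation)
        truth.parenchyma_masks[scan] = LungMask(paren, geom.spacing, geom.origin, geom.orientation)

    # truth maps on the end-inspiratory (reference) grid
    ins_paren = truth.parenchyma_masks["end_ins_pre"].mask
    enh = np.zeros(geom.shape)
    enh[ins_paren] = truth.enhancement_at(pts.reshape(geom.shape + (3,))[ins_paren])
    truth.enhancement = ImageVolume(enh, geom.spacing, geom.origin, geom.orientation)
    slope = np.zeros(geom.shape)
    intercept = np.zeros(geom.shape)
    s, i0 = truth.hu_line(pts.reshape(geom.shape + (3,))[ins_paren])
    slope[ins_paren] = s
    intercept[ins_paren] = i0
    truth.slope = ImageVolume(slope, geom.spacing, geom.origin, geom.orientation)
    truth.intercept = ImageVolume(intercept, geom.spacing, geom.origin, geom.orientation)

    truth.landmarks = sample_landmarks(truth, 50, seed=spec.seed)
    return scans, truth


def sample_landmarks(
    truth: PhantomTruth,
    n: int,
    seed: int = 0,
    fixed: str = "end_ins_pre",
    moving: str = "end_ins_post",
) -> LandmarkSet:
    """Sample ``n`` paired landmarks inside the lungs for a scan pair.

    Points are drawn uniformly from the lung interior (10% radial margin,
    clear of vessels) in material coordinates and mapped exactly through the
    truth deformations, so pairs satisfy the truth field to the inversion
    tolerance (≪0.01 mm).
    """
    if n < 1:
        raise SpecError(f"need at least one landmark, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 55]))
    semi = truth.spec.reference_semiaxes()
    centers = truth._lobe_centers()
    accepted = []
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > 2000 * n:
            raise SpecError(f"could not place {n} landmarks inside the lung")
        center = centers[int(rng.integers(2))]
        cand = center + rng.uniform(-1, 1, size=3) * semi
        q = (((cand - center) / semi) ** 2).sum()
        if q > 0.9**2:
            continue
        if truth.vessel_distance(cand[None, :]) <= 2.0:
            continue
        accepted.append(cand)
    u = np.array(accepted)
    fixed_pts = truth.phi(u, fixed)
    moving_pts = truth.phi(u, moving)
    labels = [f"L{i:03d}" for i in range(n)]
    return LandmarkSet(fixed=fixed_pts, moving=moving_pts, labels=labels)


# ---------------------------------------------------------------------------
# analytic expectations (quadrature over the continuous geometry; independent
# of the voxel pipeline)
# ---------------------------------------------------------------------------

def expected_mean_enhancement(spec: PhantomSpec) -> float:
    """Lung-mean enhancement implied by the spec (defect-free geometry).

    The gradient is antisymmetric about the lung midplane, so the mean equals
    the baseline ``e0`` exactly for a defect-free spec.
    """
    if spec.defects:
        raise ContractError("analytic mean is only defined for defect-free specs")
    return float(spec.e0)


def expected_slab_gradient(spec: PhantomSpec, n_rois: int = 5) -> tuple[float, np.ndarray]:
    """Analytic expectation of the coronal-slab regression slope.

    The coronal-slab estimator does not recover the raw per-unit-distance
    gradient parameter: slab means are weighted averages over the parenchymal
    cross-section (an ellipsoid chord-area profile with vessel exclusions),
    whose centroids are not the slab centres, and the masked extent is inset
    from the geometric lung surface.  This function computes the expectation
    of the estimator by fine quadrature of the enhancement field over the
    continuous material-space parenchyma geometry — independent of scan
    synthesis, resampling, and the imaging pipeline — and returns the slope
    an ordinary regression of slab means on slab centres (k+0.5)/n recovers,
    together with the expected slab means (ventral to dorsal).
    """
    truth = _build_truth(spec)
    semi = spec.reference_semiaxes()
    axis = _vd_axis(spec.orientation)
    margin = max(spec.spacing)

    # quadrature grid over the lobes, deliberately finer than (and not
    # aligned with) the scan voxel grid
    step = 1.2
    lo = np.array([-spec.lobe_offset_mm - semi[0], -semi[1], -semi[2]]) - 2.0
    hi = -lo
    axes = [np.arange(lo[i], hi[i] + step, step) for i in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d = _ellipsoid_signed_distance(pts, truth._lobe_centers(), semi)
    keep = d <= truth.edge_shift_mm - _W_LUNG - margin
    pts = pts[keep]
    pts = pts[truth.vessel_distance(pts) >= _W_VESSEL + margin]

    # slab extent: the extreme masked voxel centres of the spec's scan grid
    coord = pts[:, axis]
    grid = spec.grid_geometry().world_coords()[axis]
    y_lim = semi[axis] + truth.edge_shift_mm - _W_LUNG - margin
    centers_in = grid[np.abs(grid) <= y_lim]
    y_lo, y_hi = float(centers_in.min()), float(centers_in.max())

    e = truth.enhancement_at(pts)
    if spec.orientation[axis].startswith("dorsal"):
        coord = -coord
    slab = np.clip(((coord - y_lo) / (y_hi - y_lo) * n_rois).astype(int), 0, n_rois - 1)
    means = np.array([e[slab == k].mean() for k in range(n_rois)])
    centers = (np.arange(n_rois) + 0.5) / n_rois
    xc = centers - centers.mean()
    slope = float((xc * (means - means.mean())).sum() / (xc**2).sum())
    return slope, means
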