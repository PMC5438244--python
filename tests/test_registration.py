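"""Similarity metrics, bending energy, Jacobian diagnostics, and registration."""

import numpy as np
import pytest

from ctperf.core import BSplineTransform, DisplacementField, ImageVolume
from ctperf.errors import ContractError
from ctperf.registration import (
    RegistrationConfig,
    _LevelProblem,
    bending_energy,
    count_singularities,
    jacobian_determinant,
    register,
    similarity_mi,
    similarity_ncc,
)
from ctperf.segmentation import LungMask

from conftest import make_volume


def _full_mask(shape, spacing=(1.0, 1.0, 1.0)):
    return LungMask(np.ones(shape, dtype=bool), spacing)


class TestNCC:
    def test_identical_images_score_minus_one(self, rng):
        vol = make_volume(rng.normal(size=(6, 6, 6)))
        assert similarity_ncc(vol, vol, _full_mask(vol.shape)) == pytest.approx(-1.0)

    def test_negated_image_scores_plus_one(self, rng):
        vol = make_volume(rng.normal(size=(6, 6, 6)))
        neg = make_volume(-vol.voxels + 42.0)
        assert similarity_ncc(vol, neg, _full_mask(vol.shape)) == pytest.approx(1.0)

    def test_affinely_related_values(self):
        a = make_volume(np.array([1.0, 2, 3, 4, 5]).reshape(5, 1, 1))
        b = make_volume(np.array([2.0, 4, 6, 8, 10]).reshape(5, 1, 1))
        assert similarity_ncc(a, b, _full_mask((5, 1, 1))) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        const = make_volume(np.zeros((4, 4, 4)))
        with pytest.raises(ContractError):
            similarity_ncc(const, const, _full_mask((4, 4, 4)))


class TestMI:
    def test_self_mi_equals_marginal_entropy(self, rng):
        """Oracle: MI(X, X) is the entropy of the marginal histogram."""
        vol = make_volume(rng.normal(size=(16, 16, 16)))
        score = similarity_mi(vol, vol, _full_mask(vol.shape), bins=32)
        counts, _ = np.histogram(vol.voxels.ravel(), bins=32)
        p = counts[counts > 0] / counts.sum()
        entropy = float(-(p * np.log(p)).sum())
        assert score == pytest.approx(-entropy, abs=1e-12)

    def test_independent_images_have_near_zero_mi(self, rng):
        a = make_volume(rng.random((40, 40, 40)))
        b = make_volume(rng.random((40, 40, 40)))
        score = similarity_mi(a, b, _full_mask((40, 40, 40)), bins=32)
        # finite-sample bias of the plug-in estimator is (B-1)^2 / 2N
        assert -score < 0.03

    def test_constant_image_gives_zero(self, rng):
        const = make_volume(np.full((8, 8, 8), 5.0))
        other = make_volume(rng.normal(size=(8, 8, 8)))
        assert similarity_mi(const, other, _full_mask((8, 8, 8))) == pytest.approx(0.0)

    def test_pv_weighting_close_to_hard(self, rng):
        vol = make_volume(rng.normal(size=(16, 16, 16)))
        other = make_volume(vol.voxels + rng.normal(0, 0.3, vol.shape))
        hard = similarity_mi(vol, other, _full_mask(vol.shape), weighting="hard")
        pv = similarity_mi(vol, other, _full_mask(vol.shape), weighting="pv")
        assert pv == pytest.approx(hard, abs=0.3)


class TestBendingEnergy:
    def _domain(self, spacing=(1.0, 1.0, 1.0)):
        return make_volume(np.zeros((16, 16, 16)), spacing=spacing)

    def test_zero_transform_is_zero(self):
        t = BSplineTransform.identity(self._domain(), (4.0, 4.0, 4.0))
        assert bending_energy(t) == 0.0

    def test_translation_is_in_null_space(self):
        t = BSplineTransform.identity(self._domain(), (4.0, 4.0, 4.0))
        t.coefficients[..., 0] = 5.0
        t.coefficients[..., 2] = -3.0
        assert bending_energy(t) == pytest.approx(0.0, abs=1e-20)

    def test_quadratic_displacement_matches_closed_form(self):
        """d(x) = a x² along one axis: the integrand is (2a)² everywhere, so
        the per-sample mean is 4a² (times the voxel-normalisation factor)."""
        spacing = (1.0, 1.0, 1.0)
        domain = self._domain(spacing)
        t = BSplineTransform.identity(domain, (3.0, 3.0, 3.0))
        a = 0.02
        # quasi-interpolant c_k = g(u_k) − (h²/6) g''(u_k) reproduces cubics
        xs = (t.grid_origin[0]
              + t.grid_spacing[0] * np.arange(t.coefficients.shape[0]))
        coeff_x = a * xs**2 - (t.grid_spacing[0] ** 2 / 6.0) * 2 * a
        t.coefficients[..., 0] = coeff_x[:, None, None]
        expected = 4 * a**2 * spacing[0] ** 4
        assert bending_energy(t) == pytest.approx(expected, rel=0.01)

    def test_invariant_under_added_translation(self, rng):
        domain = self._domain()
        t = BSplineTransform.identity(domain, (4.0, 4.0, 4.0))
        t.coefficients = rng.normal(0, 1.0, t.coefficients.shape)
        before = bending_energy(t)
        t.coefficients = t.coefficients + np.array([2.0, -1.0, 0.5])
        assert bending_energy(t) == pytest.approx(before, rel=1e-12)


class TestJacobian:
    def _linear_field(self, shape, matrix, spacing=(1.0, 1.0, 1.0)):
        vol = make_volume(np.zeros(shape), spacing=spacing)
        g = vol.world_grid()
        vec = g @ np.asarray(matrix).T
        return DisplacementField(vec, spacing)

    def test_zero_field_gives_unit_determinant(self):
        field = DisplacementField(np.zeros((8, 8, 8, 3)), (1.0, 1.0, 1.0))
        assert np.allclose(jacobian_determinant(field).voxels, 1.0)

    def test_uniform_scaling(self):
        field = self._linear_field((8, 8, 8), np.diag([0.5, 0.0, 0.0]))
        jac = jacobian_determinant(field)
        assert np.allclose(jac.voxels, 1.5)

    def test_folding_field_is_negative_and_counted(self):
        field = self._linear_field((8, 8, 8), np.diag([-2.0, 0.0, 0.0]))
        jac = jacobian_determinant(field)
        assert np.allclose(jac.voxels, -1.0)
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask.ravel()[:10] = True
        assert count_singularities(jac, LungMask(mask, (1.0, 1.0, 1.0))) == 10

    def test_empty_mask_counts_zero(self):
        field = self._linear_field((6, 6, 6), np.diag([-2.0, 0.0, 0.0]))
        empty = LungMask(np.zeros((6, 6, 6), dtype=bool), (1.0, 1.0, 1.0))
        assert count_singularities(jacobian_determinant(field), empty) == 0


def _textured_volume(shape=(24, 24, 24), spacing=(3.5, 3.5, 3.5), shift=0.0, seed=0):
    vol = ImageVolume(np.zeros(shape), spacing, tuple(-(s - 1) * sp / 2
                                                      for s, sp in zip(shape, spacing)))
    g = vol.world_grid() + shift
    vox = (-800.0
           + 30 * np.sin(g[..., 0] / 9.0) + 25 * np.cos(g[..., 1] / 11.0)
           + 20 * np.sin(g[..., 2] / 8.0 + 1.0)
           + 15 * np.sin((g[..., 0] + g[..., 1]) / 13.0))
    return vol.with_voxels(vox)


_SMALL_CONFIG = dict(factors=(2, 1), grid_spacing_mm=(42.0, 21.0), iterations=(60, 60))


class TestRegister:
    def test_identity_registration_stays_put(self):
        vol = _textured_volume()
        mask = LungMask(np.ones(vol.shape, dtype=bool), vol.spacing)
        t, cost, log = register(vol, vol, mask, RegistrationConfig(**_SMALL_CONFIG))
        disp = np.linalg.norm(t.rasterize(vol).vectors[mask.mask], axis=1)
        assert disp.mean() <= 0.1 * max(vol.spacing)
        assert cost.similarity == pytest.approx(-1.0, abs=1e-3)

    def test_recovers_uniform_translation(self):
        fixed = _textured_volume()
        # moving(x) = pattern(x + 4), so the fixed->moving map is x -> x − 4
        moving = _textured_volume(shift=4.0)
        mask = LungMask(np.ones(fixed.shape, dtype=bool), fixed.spacing)
        t, _, _ = register(fixed, moving, mask, RegistrationConfig(**_SMALL_CONFIG))
        interior = t.rasterize(fixed).vectors[4:-4, 4:-4, 4:-4]
        assert np.allclose(interior.mean(axis=(0, 1, 2)), [-4.0, -4.0, -4.0], atol=0.7)

    def test_zero_iterations_returns_identity(self):
        vol = _textured_volume()
        mask = LungMask(np.ones(vol.shape, dtype=bool), vol.spacing)
        t, _, log = register(vol, vol, mask,
                             RegistrationConfig(factors=(1,), grid_spacing_mm=(21.0,),
                                                iterations=0))
        assert np.max(np.abs(t.coefficients)) == 0.0
        assert log[0]["iterations"] == 0

    def test_cost_never_increases(self):
        fixed = _textured_volume()
        moving = _textured_volume(shift=3.0)
        mask = LungMask(np.ones(fixed.shape, dtype=bool), fixed.spacing)
        _, _, log = register(fixed, moving, mask, RegistrationConfig(**_SMALL_CONFIG))
        for level in log:
            assert level["cost_end"] <= level["cost_start"] + 1e-12
            trace = np.asarray(level["trace"])
            assert np.all(np.diff(trace) <= 1e-9)

    def test_bit_reproducible(self):
        fixed = _textured_volume()
        moving = _textured_volume(shift=2.0)
        mask = LungMask(np.ones(fixed.shape, dtype=bool), fixed.spacing)
        cfg = RegistrationConfig(**_SMALL_CONFIG)
        t1, _, _ = register(fixed, moving, mask, cfg)
        t2, _, _ = register(fixed, moving, mask, cfg)
        assert np.array_equal(t1.coefficients, t2.coefficients)

    def test_empty_mask_rejected(self):
        vol = _textured_volume()
        empty = LungMask(np.zeros(vol.shape, dtype=bool), vol.spacing)
        with pytest.raises(ContractError):
            register(vol, vol, empty)

    def test_cost_breakdown_is_consistent(self):
        fixed = _textured_volume()
        moving = _textured_volume(shift=2.0)
        mask = LungMask(np.ones(fixed.shape, dtype=bool), fixed.spacing)
        _, cost, _ = register(fixed, moving, mask, RegistrationConfig(**_SMALL_CONFIG))
        assert cost.total == pytest.approx(cost.similarity + cost.weight * cost.bending,
                                           rel=1e-12)


class TestAnalyticGradient:
    @pytest.mark.parametrize("similarity", ["ncc", "mi"])
    def test_gradient_matches_finite_differences(self, similarity, rng):
        """On smooth images the analytic gradient tracks finite differences of
        the sampled cost (exact equality is impossible because the trilinear
        intensity model and its central-difference gradient differ at second
        order)."""
        fixed = _textured_volume(shape=(16, 16, 16))
        moving = _textured_volume(shape=(16, 16, 16), shift=1.5)
        mask = np.zeros(fixed.shape, dtype=bool)
        mask[3:13, 3:13, 3:13] = True
        cfg = RegistrationConfig(similarity=similarity, factors=(1,),
                                 grid_spacing_mm=(21.0,))
        t = BSplineTransform.identity(fixed, (21.0,) * 3)
        problem = _LevelProblem(t, fixed, moving, mask, cfg)
        x0 = rng.normal(0, 0.5, t.coefficients.size)
        _, g = problem.fun(x0)
        top = np.argsort(-np.abs(g))[:6]
        eps = 1e-4
        for i in top:
            xp, xm = x0.copy(), x0.copy()
            xp[i] += eps
            xm[i] -= eps
            numeric = (problem.fun(xp)[0] - problem.fun(xm)[0]) / (2 * eps)
            assert numeric == pytest.approx(g[i], rel=0.25, abs=1e-7)
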