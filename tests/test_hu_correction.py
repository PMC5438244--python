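"""Voxel-wise HU-vs-volume model, HU correction, and subtraction perfusion."""

import logging

import numpy as np
import pytest

from ctperf.core import DisplacementField
from ctperf.errors import ContractError
from ctperf.hu_correction import (
    PerfusionMap,
    build_aligned_stack,
    compute_perfusion,
    correct_hu,
    fit_hu_volume_model,
    negative_fraction,
)
from ctperf.phantom import sample_landmarks
from ctperf.segmentation import LungMask
from ctperf.core import warp

from conftest import make_volume


def _mask(shape, spacing=(1.0, 1.0, 1.0)):
    return LungMask(np.ones(shape, dtype=bool), spacing)


def _stack(values, shape=(3, 3, 3)):
    return tuple(make_volume(np.full(shape, v)) for v in values)


class TestFitModel:
    def test_three_point_ols_oracle(self):
        """Hand OLS for HU (−700, −800, −850) at volumes (1000, 1500, 2000):
        slope = Σ(V−V̄)(H−H̄)/Σ(V−V̄)² = −0.15 HU/cm³,
        intercept = H̄ − slope·V̄ = −783.33 + 0.15·1500 = −558.333 HU."""
        model = fit_hu_volume_model(_stack((-700.0, -800.0, -850.0)),
                                    (1000.0, 1500.0, 2000.0), _mask((3, 3, 3)))
        assert np.allclose(model.slope[model.mask.mask], -0.15, atol=1e-12)
        assert np.allclose(model.intercept[model.mask.mask], -2350 / 3 + 225.0,
                           atol=1e-9)

    def test_collinear_points_interpolated_exactly(self, noiseless_phantom):
        _, _, truth = noiseless_phantom
        aligned = truth.aligned_noiseless_hu()
        volumes = tuple(truth.volumes[s]
                        for s in ("end_exp_pre", "mid_ins_pre", "end_ins_pre"))
        model = fit_hu_volume_model(
            tuple(aligned[s] for s in ("end_exp_pre", "mid_ins_pre", "end_ins_pre")),
            volumes, truth.parenchyma_masks["end_ins_pre"])
        m = model.mask.mask
        rel = np.abs((model.slope[m] - truth.slope.voxels[m]) / truth.slope.voxels[m])
        assert rel.max() < 1e-9

    def test_outside_mask_is_flagged_not_zero(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        model = fit_hu_volume_model(_stack((-700.0, -800.0, -850.0)),
                                    (1000.0, 1500.0, 2000.0),
                                    LungMask(mask, (1.0, 1.0, 1.0)))
        pred = model.predict(1500.0)
        assert np.isfinite(pred[1, 1, 1])
        assert np.isnan(pred[0, 0, 0])

    def test_duplicate_volumes_rejected(self):
        with pytest.raises(ContractError):
            fit_hu_volume_model(_stack((-700.0, -800.0, -850.0)),
                                (1000.0, 1000.0, 2000.0), _mask((3, 3, 3)))


class TestCorrectHU:
    def test_linear_evaluation(self):
        # line with slope −0.15 HU/cm³ and intercept −562.5 HU at 2100 cm³
        shape = (2, 2, 2)
        mask = _mask(shape)
        model = fit_hu_volume_model(
            _stack((-562.5 - 0.15 * 1000, -562.5 - 0.15 * 1500, -562.5 - 0.15 * 2000),
                   shape),
            (1000.0, 1500.0, 2000.0), mask)
        out = correct_hu(make_volume(np.zeros(shape)), model, 2100.0)
        assert np.allclose(out.voxels, -877.5, atol=1e-9)

    def test_identity_at_fit_volume_for_collinear_inputs(self, noiseless_phantom):
        _, _, truth = noiseless_phantom
        aligned = truth.aligned_noiseless_hu()
        volumes = tuple(truth.volumes[s]
                        for s in ("end_exp_pre", "mid_ins_pre", "end_ins_pre"))
        mask = truth.parenchyma_masks["end_ins_pre"]
        model = fit_hu_volume_model(
            tuple(aligned[s] for s in ("end_exp_pre", "mid_ins_pre", "end_ins_pre")),
            volumes, mask)
        out = correct_hu(aligned["end_ins_pre"], model, volumes[2])
        m = mask.mask
        assert np.max(np.abs(out.voxels[m] - aligned["end_ins_pre"].voxels[m])) < 1e-9

    def test_untouched_outside_mask(self):
        shape = (3, 3, 3)
        mask = np.zeros(shape, dtype=bool)
        mask[1, 1, 1] = True
        model = fit_hu_volume_model(_stack((-700.0, -800.0, -850.0)),
                                    (1000.0, 1500.0, 2000.0),
                                    LungMask(mask, (1.0, 1.0, 1.0)))
        original = make_volume(np.full(shape, 123.0))
        out = correct_hu(original, model, 1800.0)
        assert out.voxels[0, 0, 0] == 123.0
        assert out.voxels[1, 1, 1] != 123.0

    def test_extrapolation_is_logged(self, caplog):
        model = fit_hu_volume_model(_stack((-700.0, -800.0, -850.0)),
                                    (1000.0, 1500.0, 2000.0), _mask((3, 3, 3)))
        with caplog.at_level(logging.WARNING, logger="ctperf.hu_correction"):
            correct_hu(make_volume(np.zeros((3, 3, 3))), model, 2400.0)
        assert any("extrapolat" in rec.message for rec in caplog.records)

    def test_invalid_target_rejected(self):
        model = fit_hu_volume_model(_stack((-700.0, -800.0, -850.0)),
                                    (1000.0, 1500.0, 2000.0), _mask((3, 3, 3)))
        with pytest.raises(ContractError):
            correct_hu(make_volume(np.zeros((3, 3, 3))), model, 0.0)


class TestPerfusion:
    def test_constant_shift(self, rng):
        pre = make_volume(rng.normal(-800, 20, (6, 6, 6)))
        post = make_volume(pre.voxels + 35.0)
        perf = compute_perfusion(pre, post, _mask((6, 6, 6)))
        assert np.allclose(perf.values(), 35.0)
        assert negative_fraction(perf) == 0.0
        assert perf.mean == pytest.approx(35.0)

    def test_null_contrast(self, rng):
        pre = make_volume(rng.normal(-800, 20, (6, 6, 6)))
        perf = compute_perfusion(pre, pre, _mask((6, 6, 6)))
        assert np.all(perf.values() == 0.0)
        assert negative_fraction(perf) == 0.0  # zeros count as non-negative

    def test_negative_fraction_arithmetic(self):
        enh = np.zeros((100, 1, 1))
        enh[:15] = -1.0
        perf = PerfusionMap(make_volume(enh), _mask((100, 1, 1)))
        assert negative_fraction(perf) == pytest.approx(0.15)
        assert perf.negative_count == 15

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ContractError):
            compute_perfusion(make_volume(np.zeros((4, 4, 4))),
                              make_volume(np.zeros((5, 4, 4))), _mask((4, 4, 4)))


class TestAlignedStack:
    def test_identity_transforms_pass_through(self, default_phantom):
        _, scans, _ = default_phantom
        zero = DisplacementField.zero_like(scans["end_ins_pre"])
        exp_a, mid_a, ins_a = build_aligned_stack(
            scans["end_exp_pre"], scans["mid_ins_pre"], scans["end_ins_pre"],
            zero, zero)
        assert np.array_equal(exp_a.voxels, scans["end_exp_pre"].voxels)
        assert np.array_equal(mid_a.voxels, scans["mid_ins_pre"].voxels)
        assert ins_a is scans["end_ins_pre"]

    def test_truth_transforms_align_to_half_voxel(self, noiseless_phantom):
        """The composed end-expiration mapping agrees with the exact truth
        correspondence to well under half a voxel at landmark positions."""
        _, scans, truth = noiseless_phantom
        from ctperf.core import compose_fields

        f_mid_ins = truth.displacement_field("end_ins_pre", "mid_ins_pre")
        f_exp_mid = truth.displacement_field("mid_ins_pre", "end_exp_pre")
        composed = compose_fields(outer=f_exp_mid, inner=f_mid_ins)
        lm = sample_landmarks(truth, 60, seed=9, fixed="end_ins_pre",
                              moving="end_exp_pre")
        exact = truth.displacement_at(lm.fixed, "end_ins_pre", "end_exp_pre")
        err = np.linalg.norm(composed.displacement_at(lm.fixed) - exact, axis=1)
        assert err.max() <= 0.5 * max(scans["end_ins_pre"].spacing)

    def test_composed_resampling_beats_sequential(self, noiseless_phantom):
        """One interpolation through the composed field loses no more than the
        double-resampling chain, evaluated against the analytic aligned scan."""
        _, scans, truth = noiseless_phantom
        f_mid_ins = truth.displacement_field("end_ins_pre", "mid_ins_pre")
        f_exp_mid = truth.displacement_field("mid_ins_pre", "end_exp_pre")
        exp_composed, _, _ = build_aligned_stack(
            scans["end_exp_pre"], scans["mid_ins_pre"], scans["end_ins_pre"],
            f_exp_mid, f_mid_ins)
        sequential = warp(warp(scans["end_exp_pre"], f_exp_mid), f_mid_ins)
        exact = truth.aligned_noiseless_hu()["end_exp_pre"]
        m = truth.parenchyma_masks["end_ins_pre"].mask
        err_composed = np.abs(exp_composed.voxels[m] - exact.voxels[m]).mean()
        err_sequential = np.abs(sequential.voxels[m] - exact.voxels[m]).mean()
        assert err_composed <= err_sequential
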