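"""Volume/transform data model: I/O round trips, warping, pyramids, composition."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from ctperf.core import (
    BSplineTransform,
    DisplacementField,
    ImageVolume,
    compose_fields,
    gaussian_pyramid,
    read_volume,
    warp,
    write_volume,
)
from ctperf.errors import ContractError, FormatError, ParseError

from conftest import make_volume


class TestVolumeIO:
    @pytest.mark.parametrize("suffix", [".nii", ".nii.gz", ".mha", ".mhd"])
    def test_round_trip_is_lossless(self, tmp_path, rng, suffix):
        vol = ImageVolume(
            rng.normal(-500, 300, (8, 8, 8)),
            spacing=(1.0, 1.0, 1.25),
            origin=(-3.5, -3.5, -4.375),
            orientation=("left-right", "dorsal-ventral", "cranial-caudal"),
        )
        path = tmp_path / f"vol{suffix}"
        write_volume(vol, path)
        back = read_volume(path)
        assert np.max(np.abs(back.voxels - vol.voxels)) == 0.0
        assert np.allclose(back.spacing, vol.spacing, atol=1e-6)
        assert back.spacing[2] == pytest.approx(1.25, abs=1e-9)
        assert np.allclose(back.origin, vol.origin, atol=1e-6)
        assert back.orientation == vol.orientation

    def test_constant_volume_round_trip(self, tmp_path):
        vol = make_volume(np.full((4, 4, 4), -1000.0))
        path = tmp_path / "air.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        assert np.array_equal(back.voxels, vol.voxels)

    def test_unsupported_format_rejected(self, tmp_path):
        with pytest.raises(FormatError):
            read_volume(tmp_path / "vol.png")

    def test_empty_file_is_parse_error(self, tmp_path):
        path = tmp_path / "broken.nii"
        path.write_bytes(b"")
        with pytest.raises(ParseError):
            read_volume(path)

    def test_missing_parent_directory_is_io_error(self, tmp_path):
        vol = make_volume(np.zeros((4, 4, 4)))
        with pytest.raises(OSError):
            write_volume(vol, tmp_path / "nope" / "vol.nii")

    def test_invariants_rejected(self):
        with pytest.raises(ContractError):
            ImageVolume(np.zeros((4, 4, 4)), spacing=(0.0, 1.0, 1.0))
        with pytest.raises(ContractError):
            ImageVolume(np.full((4, 4, 4), np.nan), spacing=(1.0, 1.0, 1.0))
        with pytest.raises(ContractError):
            ImageVolume(np.zeros((4, 4, 4)), spacing=(1, 1, 1),
                        orientation=("right-left", "right-left", "cranial-caudal"))


class TestWarp:
    def test_zero_field_is_identity(self, rng):
        vol = make_volume(rng.normal(size=(10, 11, 12)))
        out = warp(vol, DisplacementField.zero_like(vol))
        assert np.array_equal(out.voxels, vol.voxels)

    def test_uniform_shift_of_ramp(self):
        # ramp along axis 0; +1 voxel displacement samples the next slice
        shape = (12, 6, 6)
        ramp = np.broadcast_to(np.arange(12, dtype=float)[:, None, None], shape).copy()
        vol = make_volume(ramp, spacing=(2.0, 1.0, 1.0))
        field = DisplacementField(
            np.stack([np.full(shape, 2.0), np.zeros(shape), np.zeros(shape)], axis=-1),
            spacing=vol.spacing,
        )
        out = warp(vol, field)
        assert np.allclose(out.voxels[:-1], ramp[:-1] + 1.0)

    def test_nearest_keeps_masks_binary(self, rng):
        mask = (rng.random((8, 8, 8)) > 0.5).astype(float)
        vol = make_volume(mask)
        vec = rng.normal(0, 0.4, (8, 8, 8, 3))
        out = warp(vol, DisplacementField(vec, vol.spacing), interpolation="nearest",
                   fill_value=0.0)
        assert set(np.unique(out.voxels)) <= {0.0, 1.0}

    def test_outside_samples_take_fill_value(self):
        vol = make_volume(np.full((4, 4, 4), 100.0))
        vec = np.full((4, 4, 4, 3), 50.0)  # everything maps far outside
        out = warp(vol, DisplacementField(vec, vol.spacing))
        assert np.all(out.voxels == -1000.0)

    def test_orientation_mismatch_rejected(self):
        vol = make_volume(np.zeros((4, 4, 4)))
        field = DisplacementField(
            np.zeros((4, 4, 4, 3)), vol.spacing,
            orientation=("left-right", "ventral-dorsal", "cranial-caudal"),
        )
        with pytest.raises(ContractError):
            warp(vol, field)


class TestGaussianPyramid:
    def test_clinical_schedule_shapes(self, rng):
        vol = make_volume(rng.normal(size=(64, 64, 64)))
        levels = gaussian_pyramid(vol, [16, 8, 4, 2, 1])
        assert [lv.shape for lv in levels] == [(4,) * 3, (8,) * 3, (16,) * 3,
                                               (32,) * 3, (64,) * 3]
        for lv, f in zip(levels, [16, 8, 4, 2, 1]):
            assert np.allclose(lv.spacing, np.asarray(vol.spacing) * f, atol=1e-9)

    def test_constant_volume_stays_constant(self):
        vol = make_volume(np.full((32, 32, 32), -700.0))
        for lv in gaussian_pyramid(vol, [8, 2, 1]):
            assert np.allclose(lv.voxels, -700.0)

    def test_factor_one_is_identity(self, rng):
        vol = make_volume(rng.normal(size=(8, 8, 8)))
        (lv,) = gaussian_pyramid(vol, [1])
        assert np.array_equal(lv.voxels, vol.voxels)

    def test_bad_factors_rejected(self, rng):
        vol = make_volume(rng.normal(size=(8, 8, 8)))
        with pytest.raises(ContractError):
            gaussian_pyramid(vol, [2, 4])  # increasing
        with pytest.raises(ContractError):
            gaussian_pyramid(vol, [16])  # exceeds extent


class TestComposeFields:
    def test_zero_is_identity_element(self, rng):
        vol = make_volume(np.zeros((8, 8, 8)), spacing=(2.0, 2.0, 2.0))
        zero = DisplacementField.zero_like(vol)
        f = DisplacementField(rng.normal(0, 1.5, (8, 8, 8, 3)), vol.spacing)
        assert np.max(np.abs(compose_fields(zero, f).vectors - f.vectors)) <= 1e-9
        assert np.max(np.abs(compose_fields(f, zero).vectors - f.vectors)) <= 1e-9

    def test_translations_compose_additively(self):
        vol = make_volume(np.zeros((6, 6, 6)))
        a = DisplacementField(np.broadcast_to([1.0, -2.0, 0.5], (6, 6, 6, 3)).copy(),
                              vol.spacing)
        b = DisplacementField(np.broadcast_to([0.25, 1.0, -0.75], (6, 6, 6, 3)).copy(),
                              vol.spacing)
        out = compose_fields(a, b)
        assert np.allclose(out.vectors, np.broadcast_to([1.25, -1.0, -0.25],
                                                        (6, 6, 6, 3)), atol=1e-12)

    def test_matches_pointwise_oracle(self, rng):
        # independent oracle: evaluate inner then interpolate outer with scipy
        shape = (12, 12, 12)
        spacing = (3.0, 3.0, 3.0)
        vol = make_volume(np.zeros(shape), spacing=spacing)
        coords = vol.world_coords()

        def smooth_field(seed):
            r = np.random.default_rng(seed)
            g = vol.world_grid()
            vec = np.stack([
                2.0 * np.sin(g[..., 0] / 11 + r.uniform(0, 6))
                + 1.5 * np.cos(g[..., 1] / 13),
                1.0 * np.sin(g[..., 2] / 9 + r.uniform(0, 6)),
                1.2 * np.cos(g[..., 0] / 15) * np.sin(g[..., 1] / 12),
            ], axis=-1)
            return DisplacementField(vec, spacing)

        inner, outer = smooth_field(1), smooth_field(2)
        result = compose_fields(outer, inner)
        interp = [RegularGridInterpolator(coords, outer.vectors[..., v],
                                          bounds_error=False, fill_value=None)
                  for v in range(3)]
        pts_idx = rng.integers(2, 10, size=(100, 3))
        for i, j, k in pts_idx:
            x = np.array([coords[0][i], coords[1][j], coords[2][k]])
            mid = x + inner.vectors[i, j, k]
            expected = inner.vectors[i, j, k] + np.array([f(mid)[0] for f in interp])
            assert np.allclose(result.vectors[i, j, k], expected, atol=1e-9)


class TestBSplineTransform:
    def test_rasterize_matches_pointwise_evaluation(self, rng):
        vol = make_volume(np.zeros((10, 10, 10)), spacing=(4.0, 4.0, 4.0))
        t = BSplineTransform.identity(vol, (12.0, 12.0, 12.0))
        t.coefficients = rng.normal(0, 2.0, t.coefficients.shape)
        field = t.rasterize(vol)
        pts = vol.world_grid().reshape(-1, 3)[::37]
        direct = t.displacement_at(pts)
        sampled = field.vectors.reshape(-1, 3)[::37]
        assert np.allclose(direct, sampled, atol=1e-10)

    def test_identity_transform_is_zero(self):
        vol = make_volume(np.zeros((8, 8, 8)))
        t = BSplineTransform.identity(vol, (4.0, 4.0, 4.0))
        assert np.max(np.abs(t.rasterize(vol).vectors)) == 0.0
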