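"""Demodulation, stitching and illumination correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wvtomo import (AcquisitionPlan, CorrectionModel, apply_lateral_correction,
                    demodulate, equalize_axial, fit_lateral_correction, pipeline,
                    stitch_section, widefield)
from wvtomo.scope_sim import RawTile


def _frames(B, A, phi, shape=(5, 5)):
    return [np.full(shape, B + A * np.cos(phi + k * np.pi / 2)) for k in range(3)]


class TestDemodulate:
    @pytest.mark.parametrize("phi", [0.0, np.pi / 4])
    def test_recovers_amplitude(self, phi):
        out = demodulate(*_frames(100.0, 50.0, phi))
        assert np.allclose(out, 50.0, atol=1e-12)

    def test_constant_frames_fully_rejected(self):
        out = demodulate(*[np.full((4, 4), 7.0)] * 3)
        assert np.allclose(out, 0.0)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        B=st.floats(min_value=0.0, max_value=1e6),
        frac=st.floats(min_value=0.0, max_value=1.0),
        phi=st.floats(min_value=-10.0, max_value=10.0),
        ambient=st.floats(min_value=0.0, max_value=1e5),
    )
    def test_exactness_and_background_invariance(self, B, frac, phi, ambient):
        """A is recovered to machine precision for any B >= A >= 0 and phase."""
        A = frac * B
        base = _frames(B, A, phi, shape=(2, 2))
        out = demodulate(*base)
        assert np.allclose(out, A, rtol=1e-9, atol=1e-9 * max(B, 1.0))
        out2 = demodulate(*[f + ambient for f in base])
        assert np.allclose(out, out2, rtol=1e-9, atol=1e-9 * max(B + ambient, 1.0))

    def test_rms_estimator_exact_for_2pi3_step(self):
        B, A, phi = 80.0, 30.0, 0.7
        frames = [np.full((3, 3), B + A * np.cos(phi + k * 2 * np.pi / 3))
                  for k in range(3)]
        out = demodulate(*frames, method="rms_2pi3")
        assert np.allclose(out, A, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            demodulate(np.ones((3, 3)), np.ones((3, 3)), np.ones((4, 3)))


class TestWidefield:
    def test_equals_background(self):
        assert np.allclose(widefield(*_frames(100.0, 50.0, 0.0)), 100.0)

    @pytest.mark.parametrize("c", [0.0, 3.5])
    def test_constant_frames(self, c):
        assert np.allclose(widefield(*[np.full((2, 2), c)] * 3), c)


def _grid_plan(fov=40, overlap=8.0):
    return AcquisitionPlan(fov_pixels=(fov, fov), pixel_size_um=1.0,
                           overlap_um=overlap, z_planes_per_section=1,
                           z_step_um=4.0, section_thickness_um=4.0)


class TestStitch:
    def test_single_tile_identity(self):
        plan = _grid_plan()
        img = np.random.default_rng(0).random((40, 40))
        out = stitch_section({(0, 0): img}, plan)
        assert np.array_equal(out.pixels, img)

    def test_constant_tiles_feather_to_constant(self):
        plan = _grid_plan()
        tiles = {(ix, iy): np.full((40, 40), 7.0) for ix in range(3) for iy in range(2)}
        out = stitch_section(tiles, plan)
        assert np.allclose(out.pixels, 7.0, atol=1e-12)

    def test_matches_paste_oracle_on_consistent_tiles(self):
        """Tiles cropped from one scene stitch back to exactly that scene."""
        plan = _grid_plan()
        rng = np.random.default_rng(5)
        stride = 32
        scene = rng.random((40 + stride, 40 + stride))
        tiles = {(ix, iy): scene[iy * stride:iy * stride + 40,
                                 ix * stride:ix * stride + 40]
                 for ix in range(2) for iy in range(2)}
        out = stitch_section(tiles, plan)
        assert np.allclose(out.pixels, scene, atol=1e-12)

    def test_missing_tile_reported(self):
        plan = _grid_plan()
        tiles = {(0, 0): np.ones((40, 40)), (1, 1): np.ones((40, 40))}
        with pytest.raises(ValueError, match=r"missing tiles.*\(1, 0\)"):
            stitch_section(tiles, plan)

    def test_refine_noop_on_consistent_tiles(self):
        plan = _grid_plan()
        rng = np.random.default_rng(6)
        from scipy import ndimage

        scene = ndimage.gaussian_filter(rng.random((80, 80)) * 100, 2)
        stride = 32
        tiles = {(ix, iy): scene[iy * stride:iy * stride + 40,
                                 ix * stride:ix * stride + 40]
                 for ix in range(2) for iy in range(2)}
        out = stitch_section(tiles, plan, refine=True, search_radius_um=3.0)
        for off in out.tile_offsets_px.values():
            assert abs(off[0]) <= 0.5 and abs(off[1]) <= 0.5


class TestLateralCorrection:
    def test_flat_image_unit_gain(self):
        model = fit_lateral_correction(np.full((50, 60), 42.0))
        gx, gy = model.gain_profiles()
        assert np.allclose(gx, 1.0, atol=1e-9)
        assert np.allclose(gy, 1.0, atol=1e-9)

    def test_parabolic_vignette_restored_within_1pct(self):
        ny, nx = 120, 140
        cy, cx = (ny - 1) / 2, (nx - 1) / 2
        vx = 1.0 - 0.3 * ((np.arange(nx) - cx) / cx) ** 2
        vy = 1.0 - 0.3 * ((np.arange(ny) - cy) / cy) ** 2
        img = 100.0 * np.outer(vy, vx)
        model = fit_lateral_correction(img, degree=4)
        corrected = apply_lateral_correction(img, model)
        col_means = corrected.mean(axis=0)
        row_means = corrected.mean(axis=1)
        assert np.ptp(col_means) / col_means.mean() < 0.01
        assert np.ptp(row_means) / row_means.mean() < 0.01

    def test_degree_zero_is_unit_gain(self):
        rng = np.random.default_rng(2)
        model = fit_lateral_correction(rng.random((30, 30)) + 0.5, degree=0)
        gx, gy = model.gain_profiles()
        assert np.allclose(gx, 1.0, atol=1e-12)
        assert np.allclose(gy, 1.0, atol=1e-12)

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError):
            fit_lateral_correction(np.zeros((20, 20)))

    def test_apply_unit_model_identity_and_domain_check(self):
        img = np.random.default_rng(3).random((20, 25))
        model = fit_lateral_correction(np.full((20, 25), 5.0))
        assert np.allclose(apply_lateral_correction(img, model), img)
        with pytest.raises(ValueError, match="domain"):
            apply_lateral_correction(np.ones((10, 10)), model)
        assert np.array_equal(
            apply_lateral_correction(np.zeros((20, 25)), model), np.zeros((20, 25)))


class TestEqualizeAxial:
    def test_reference_mapping(self):
        out, gains = equalize_axial(
            [np.full((8, 8), 100.0), np.full((8, 8), 50.0)], reference_level=100.0)
        assert gains == [1.0, 2.0]
        assert np.allclose(out[1], 100.0)

    def test_identical_sections_unit_gains(self):
        secs = [np.full((8, 8), 9.0)] * 4
        _, gains = equalize_axial(secs)
        assert gains == [1.0] * 4

    def test_single_section_unit_gain_under_median(self):
        _, gains = equalize_axial([np.full((8, 8), 3.0)])
        assert gains == [1.0]

    def test_zero_section_warns_not_raises(self):
        with pytest.warns(UserWarning, match="zero"):
            _, gains = equalize_axial([np.full((4, 4), 2.0), np.zeros((4, 4))])
        assert gains[1] == 1.0


class TestPipeline:
    def test_empty_manifest_rejected(self, small_plan):
        with pytest.raises(ValueError, match="empty"):
            pipeline([], small_plan)

    def test_incomplete_phase_group_identified(self, small_plan):
        t = RawTile(pixels=np.ones((64, 64)), channel="green", section_index=0,
                    z_plane_index=0, phase_index=0, tile_index=(0, 0),
                    stage_position_um=(0.0, 0.0))
        with pytest.raises(ValueError, match="section=0"):
            pipeline([t], small_plan)

    def test_round_trip_plane_count(self, small_plan, optics):
        from wvtomo import PhantomConfig, generate_phantom, run_acquisition

        cfg = PhantomConfig(volume_shape_vox=(100, 100, 26), voxel_size_um=0.325,
                            n_neurons=0, n_nuclei=2, nucleus_radius_mean_um=2.0,
                            nucleus_min_separation_um=8.0, seed=9)
        phantom = generate_phantom(cfg)
        tiles, _ = run_acquisition(phantom, small_plan, optics, seed=0)
        result = pipeline(tiles, small_plan)
        for ch in ("green", "red"):
            assert result.volumes[ch].shape[0] == 4  # 2 sections x 2 z-planes
        assert all(np.isfinite(v).all() and (v >= 0).all()
                   for v in result.volumes.values())
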