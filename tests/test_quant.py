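"""Bead metrology, soma detection, morphometry and group statistics."""

import math

import numpy as np
import pytest
from scipy import ndimage

from wvtomo import (PhantomConfig, colocalize, compare_groups, detect_somata,
                    generate_bead_phantom, generate_phantom, measure_fwhm,
                    morphometry, project)
from wvtomo.quant import FWHM_PER_SIGMA
from wvtomo.swc import APICAL, AXON, BASAL, SOMA, NeuronTree, SWCNode


def _bead_stack(sigma_lat_um, sigma_ax_um, voxel=(0.2, 0.32, 0.32),
                shape=(33, 33, 61), truncate=5.0):
    """Noiseless Gaussian bead image sampled on the metrology grid."""
    nx, ny, nz = shape
    dx, dy, dz = voxel[2], voxel[1], voxel[0]
    center = ((nx // 2 + 0.5) * dx, (ny // 2 + 0.5) * dy, (nz // 2 + 0.5) * dz)
    p = generate_bead_phantom([center], shape, (dx, dy, dz))
    return ndimage.gaussian_filter(
        p.green_density.astype(float),
        (sigma_ax_um / dz, sigma_lat_um / dy, sigma_lat_um / dx),
        truncate=truncate)


class TestMeasureFWHM:
    @pytest.mark.parametrize(
        "sig_lat,sig_ax,fwhm_lat,fwhm_ax",
        [(0.23357, 0.93426, 0.55, 2.20), (0.26330, 1.09988, 0.62, 2.59)],
    )
    def test_recovers_instrument_psf_widths(self, sig_lat, sig_ax, fwhm_lat, fwhm_ax):
        stack = _bead_stack(sig_lat, sig_ax)
        m = measure_fwhm(stack, (0.2, 0.32, 0.32))
        assert m.fwhm_lateral_um == pytest.approx(fwhm_lat, rel=0.02)
        assert m.fwhm_axial_um == pytest.approx(fwhm_ax, rel=0.02)

    def test_scale_equivariance(self):
        m1 = measure_fwhm(_bead_stack(0.3, 0.8), (0.2, 0.32, 0.32))
        m2 = measure_fwhm(_bead_stack(0.6, 1.6, shape=(49, 49, 91)), (0.2, 0.32, 0.32))
        assert m2.fwhm_lateral_um == pytest.approx(2 * m1.fwhm_lateral_um, rel=0.01)
        assert m2.fwhm_axial_um == pytest.approx(2 * m1.fwhm_axial_um, rel=0.01)

    def test_noise_robust_parameter_recovery(self, rng):
        """Median |error| < 5% over sigma in [0.2, 1.2] um with Poisson noise."""
        errors = []
        for sigma in (0.2, 0.4, 0.7, 1.0, 1.2):
            clean = _bead_stack(sigma, sigma, shape=(49, 49, 81))
            scale = 400.0 / clean.max()  # SNR = sqrt(400) = 20 at the peak
            noisy = rng.poisson(clean * scale) / scale
            m = measure_fwhm(noisy, (0.2, 0.32, 0.32))
            expected = FWHM_PER_SIGMA * sigma
            errors.append(abs(m.fwhm_lateral_um - expected) / expected)
            errors.append(abs(m.fwhm_axial_um - expected) / expected)
        assert np.median(errors) < 0.05

    def test_flat_stack_rejected(self):
        with pytest.raises(ValueError, match="maximum"):
            measure_fwhm(np.ones((10, 10, 10)), (0.2, 0.32, 0.32))


class TestDetectSomata:
    def test_phantom_nuclei_all_recovered(self, nucleus_phantom):
        p = nucleus_phantom
        det = detect_somata(p.red_affinity, (0.5, 0.5, 0.5), 1.5, 4.0)
        assert len(det) == 20
        truth = [c for c, _ in p.truth_nuclei]
        pairs, unmatched_det, unmatched_truth = colocalize(
            [c for c, _ in det], truth, 1.0)
        assert len(pairs) == 20 and not unmatched_det and not unmatched_truth

    def test_empty_volume(self):
        assert detect_somata(np.zeros((20, 20, 20)), (1, 1, 1), 1.5, 4.0) == []

    def test_colliding_nuclei_merge_to_one(self):
        """Two cells closer than the suppression distance yield one detection."""
        vol = np.zeros((40, 40, 40))
        zz, yy, xx = np.mgrid[0:40, 0:40, 0:40].astype(float)
        for c in ((20.0, 20.0, 18.0), (20.0, 20.0, 22.0)):  # 4 um apart
            d = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
            vol = np.maximum(vol, np.clip(3.0 - d + 0.5, 0, 1))
        det = detect_somata(vol, (1, 1, 1), 2.0, 4.0, suppress_dist_um=5.0)
        assert len(det) == 1

    def test_empty_radius_range_rejected(self):
        with pytest.raises(ValueError):
            detect_somata(np.ones((5, 5, 5)), (1, 1, 1), 3.0, 3.0)


class TestColocalize:
    def test_identical_lists_all_matched_at_zero(self):
        pts = [(1.0, 2.0, 3.0), (9.0, 9.0, 9.0)]
        pairs, ua, ub = colocalize(pts, pts, 0.5)
        assert [(i, j) for i, j, _ in pairs] == [(0, 0), (1, 1)]
        assert all(d == 0.0 for _, _, d in pairs)
        assert ua == [] and ub == []

    def test_disjoint_sets_no_matches(self):
        pairs, ua, ub = colocalize([(0.0, 0.0, 0.0)], [(100.0, 0.0, 0.0)], 5.0)
        assert pairs == [] and ua == [0] and ub == [0]

    def test_phantom_overlap_fraction_on_truth(self):
        cfg = PhantomConfig(volume_shape_vox=(160, 160, 48), voxel_size_um=0.5,
                            n_neurons=10, n_nuclei=12, soma_overlap_fraction=0.6,
                            seed=5)
        p = generate_phantom(cfg)
        roots = [t.root.position for t in p.truth_trees]
        nuclei = [c for c, _ in p.truth_nuclei]
        pairs, _, _ = colocalize(roots, nuclei, 1.0)
        assert len(pairs) == 6

    def test_each_center_used_once(self):
        pairs, ua, ub = colocalize([(0, 0, 0), (1, 0, 0)], [(0.4, 0, 0)], 2.0)
        assert len(pairs) == 1
        assert pairs[0][:2] == (0, 0)  # closest pair wins


def _y_tree():
    """Root soma at origin, 10 um trunk, two 5 um branches (3-4-5 geometry)."""
    rows = [
        (1, SOMA, 0.0, 0.0, 0.0, 2.0, -1),
        (2, AXON, 0.0, 0.0, 10.0, 0.5, 1),
        (3, AXON, 3.0, 0.0, 14.0, 0.5, 2),
        (4, AXON, -3.0, 0.0, 14.0, 0.5, 2),
    ]
    return NeuronTree.from_rows(rows)


class TestMorphometry:
    def test_two_node_axon(self):
        tree = NeuronTree.from_rows([
            (1, SOMA, 0, 0, 0, 2.0, -1), (2, AXON, 0, 0, 10.0, 0.5, 1)])
        r = morphometry(tree)
        assert r.axon_length_um == pytest.approx(10.0)
        assert r.axon_branch_count == 0

    def test_y_shaped_axon(self):
        r = morphometry(_y_tree())
        assert r.axon_length_um == pytest.approx(20.0)  # 10 + 2 x 5
        assert r.axon_branch_count == 1
        assert r.axon_segment_count == 3

    def test_edge_subdivision_invariance(self):
        r1 = morphometry(_y_tree())
        rows = [
            (1, SOMA, 0.0, 0.0, 0.0, 2.0, -1),
            (5, AXON, 0.0, 0.0, 4.0, 0.5, 1),  # collinear pass-through node
            (2, AXON, 0.0, 0.0, 10.0, 0.5, 5),
            (3, AXON, 3.0, 0.0, 14.0, 0.5, 2),
            (4, AXON, -3.0, 0.0, 14.0, 0.5, 2),
        ]
        r2 = morphometry(NeuronTree.from_rows(rows))
        assert r2.axon_length_um == pytest.approx(r1.axon_length_um)
        assert r2.axon_branch_count == r1.axon_branch_count

    def test_node_reindexing_invariance(self):
        rows = [
            (10, SOMA, 0.0, 0.0, 0.0, 2.0, -1),
            (7, AXON, 0.0, 0.0, 10.0, 0.5, 10),
            (99, AXON, 3.0, 0.0, 14.0, 0.5, 7),
            (2, AXON, -3.0, 0.0, 14.0, 0.5, 7),
        ]
        r = morphometry(NeuronTree.from_rows(rows))
        assert r.axon_length_um == pytest.approx(20.0)
        assert r.axon_branch_count == 1

    def test_dendrite_totals_are_apical_plus_basal(self):
        rows = [
            (1, SOMA, 0, 0, 0, 2.0, -1),
            (2, APICAL, 0, 0, 8.0, 1.0, 1),
            (3, APICAL, 0, 3.0, 12.0, 1.0, 2),
            (4, BASAL, 0, 0, -6.0, 1.0, 1),
        ]
        r = morphometry(NeuronTree.from_rows(rows))
        assert r.apical_length_um == pytest.approx(13.0)
        assert r.basal_length_um == pytest.approx(6.0)
        assert r.dendrite_length_um == pytest.approx(r.apical_length_um + r.basal_length_um)

    def test_unknown_type_counted_as_other_with_warning(self):
        rows = [(1, SOMA, 0, 0, 0, 2.0, -1), (2, 7, 0, 0, 5.0, 1.0, 1)]
        with pytest.warns(UserWarning, match="other"):
            r = morphometry(NeuronTree.from_rows(rows))
        assert r.other_length_um == pytest.approx(5.0)
        assert r.axon_length_um == 0.0

    def test_projection_classification_by_axonal_extent(self):
        rows = [(1, SOMA, 0, 0, 0, 2.0, -1)]
        for i in range(2, 60):
            rows.append((i, AXON, 20.0 * (i - 1), 0.0, 0.0, 0.5, i - 1))
        long_tree = NeuronTree.from_rows(rows)
        assert morphometry(long_tree).projection_class == "long-range"
        assert morphometry(_y_tree()).projection_class == "local"


class TestCompareGroups:
    def test_matches_pooled_variance_closed_form(self):
        a = np.array([1.0, 2.0, 3.0, 5.0])
        b = np.array([2.5, 4.0, 6.0])
        r = compare_groups(a, b)
        na, nb = len(a), len(b)
        sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert r.t_statistic == pytest.approx(t_hand, abs=1e-12)
        from scipy import stats

        assert r.p_value == pytest.approx(
            2 * stats.t.sf(abs(t_hand), na + nb - 2), abs=1e-12)
        assert r.sem_a == pytest.approx(a.std(ddof=1) / math.sqrt(na), abs=1e-12)

    def test_identical_groups(self):
        r = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0, abs=1e-12)

    def test_large_shift_tiny_variance(self):
        r = compare_groups([1.0, 1.001, 0.999], [100.0, 100.001, 99.999])
        assert r.p_value < 1e-3

    def test_degenerate_and_invalid_inputs(self):
        r = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert r.p_value == 1.0 and r.t_statistic == 0.0
        r2 = compare_groups([1.0, 1.0], [2.0, 2.0])
        assert r2.p_value == 0.0
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])

    def test_null_rejection_rate_calibrated(self, rng):
        """Type-I error at alpha = 0.05 lies in (0.03, 0.07) over 1,000 null draws."""
        rejections = 0
        for _ in range(1000):
            a = rng.normal(0.0, 1.0, size=10)
            b = rng.normal(0.0, 1.0, size=10)
            if compare_groups(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 < rejections / 1000 < 0.07


class TestProject:
    def test_single_plane_slab_identity(self, rng):
        vol = rng.random((6, 10, 10))
        assert np.array_equal(project(vol, 0, "max", (2, 3)), vol[2])
        assert np.array_equal(project(vol, 0, "min", (2, 3)), vol[2])

    def test_max_dominates_min(self, rng):
        vol = rng.random((6, 10, 10))
        assert np.all(project(vol, 0, "max") >= project(vol, 0, "min"))

    def test_empty_slab_rejected(self, rng):
        with pytest.raises(ValueError):
            project(np.ones((4, 4, 4)), 0, "max", (2, 2))

    def test_barrel_wall_contrast_in_min_projection(self):
        """A ring of nuclei keeps its wall bright through a min-projection slab."""
        cfg = PhantomConfig(volume_shape_vox=(96, 96, 24), voxel_size_um=1.0,
                            n_neurons=0, n_nuclei=0, background_level=0.0)
        p = generate_phantom(cfg)
        zz, yy, xx = np.mgrid[0:24, 0:96, 0:96].astype(float)
        r_lat = np.sqrt((yy - 48) ** 2 + (xx - 48) ** 2)
        wall = (np.abs(r_lat - 25.0) < 4.0)  # cylindrical barrel wall, all depths
        p.red_affinity[wall] = 80.0
        mip = project(p.red_affinity, 0, "min", (4, 20))
        yy2, xx2 = np.mgrid[0:96, 0:96].astype(float)
        r2 = np.sqrt((yy2 - 48) ** 2 + (xx2 - 48) ** 2)
        wall_mean = mip[np.abs(r2 - 25.0) < 2.0].mean()
        hollow_mean = mip[r2 < 15.0].mean()
        assert wall_mean > hollow_mean + 10.0
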