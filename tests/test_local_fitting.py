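"""Edge detection, ROI sampling, plane fitting and the angle distribution."""

import numpy as np
import pytest

import canostereo as cs
from canostereo import camera_geometry as cg
from canostereo import height_analysis as ha
from canostereo import local_fitting as lf


class TestDetectLeafEdges:
    def test_constant_image_has_no_edges(self):
        assert not lf.detect_leaf_edges(np.full((50, 50), 900.0)).any()

    def test_step_edge_detected_once_along_the_step(self):
        img = np.zeros((40, 60))
        img[:, 30:] = 1000.0
        edges = lf.detect_leaf_edges(img)
        cols = np.nonzero(edges)[1]
        assert len(cols) >= 30                       # a chain along the step
        assert np.all(np.abs(cols - 29.5) <= 2)      # localized at the step

    def test_two_leaf_boundary_lies_near_detected_edges(self):
        """Every boundary pixel between two rendered leaves must be within
        2 px of a Canny edge, so ROIs cannot straddle leaves."""
        from scipy.ndimage import binary_dilation

        rig = cs.SIM_RIG
        leaves = [
            cs.LeafQuad(center=np.array([-0.04, 0.0, 0.85]), width=0.1,
                        length=0.12, tilt=15.0, azimuth=0.0, color_scale=1.1),
            cs.LeafQuad(center=np.array([0.05, 0.0, 0.78]), width=0.1,
                        length=0.12, tilt=25.0, azimuth=90.0, color_scale=0.85),
        ]
        scene = cs.SceneSpec(rig=rig, ground_depth=1.05, leaves=leaves, seed=8)
        pair, depth, labels = cs.render_views(scene)
        gray = np.asarray(pair.left, float) @ np.array([0.299, 0.587, 0.114])
        edges = lf.detect_leaf_edges(gray)
        # boundary: plant pixels adjacent to the other leaf or to soil
        plant = labels == cs.LEAF
        boundary = plant & binary_dilation(~plant)
        near_edge = binary_dilation(edges, iterations=2)
        coverage = (boundary & near_edge).sum() / boundary.sum()
        assert coverage > 0.9


class TestFitPlane:
    def _tilted_points(self, tilt_deg, n=30, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-0.02, 0.02, n * n)
        y = rng.uniform(-0.02, 0.02, n * n)
        z = np.tan(np.radians(tilt_deg)) * x + rng.normal(0, noise, n * n)
        return np.column_stack([x, y, z])

    @pytest.mark.parametrize("method", ["vertical", "orthogonal"])
    def test_exact_plane_recovered_to_numerical_precision(self, method):
        pts = self._tilted_points(40.0)
        normal, rms = lf.fit_plane(pts, method=method)
        assert lf.tilt_from_normal(normal) == pytest.approx(40.0, abs=1e-9)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_small_noise_keeps_tilt_within_one_degree(self):
        pts = self._tilted_points(35.0, noise=5e-4, seed=1)  # sigma 0.5 mm, 900 pts
        normal, _ = lf.fit_plane(pts)
        assert lf.tilt_from_normal(normal) == pytest.approx(35.0, abs=1.0)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(3.0), np.arange(3.0), np.arange(3.0)])
        with pytest.raises(lf.FitError):
            lf.fit_plane(pts)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(lf.FitError):
            lf.fit_plane(np.zeros((2, 3)))

    def test_vertical_fit_survives_depth_noise_larger_than_extent(self):
        """Depth noise of a full resolution step dwarfs the ROI extent; the
        vertical fit keeps the slope unbiased where orthogonal TLS collapses
        to a ~90-degree plane."""
        pts = self._tilted_points(30.0, noise=0.015, seed=2)
        n_v, _ = lf.fit_plane(pts, method="vertical")
        tilt_v = lf.tilt_from_normal(n_v)
        n_o, _ = lf.fit_plane(pts, method="orthogonal")
        tilt_o = lf.tilt_from_normal(n_o)
        assert abs(tilt_v - 30.0) < 8.0
        assert abs(tilt_o - 30.0) > abs(tilt_v - 30.0)


class TestTiltFromNormal:
    def test_horizontal_plane(self):
        assert lf.tilt_from_normal([0, 0, 1]) == 0.0

    def test_vertical_plane(self):
        assert lf.tilt_from_normal([1, 0, 0]) == 90.0

    def test_constructed_thirty_degrees(self):
        n = [0.0, np.sin(np.radians(30)), np.cos(np.radians(30))]
        assert lf.tilt_from_normal(n) == pytest.approx(30.0, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            lf.tilt_from_normal([0, 0, 0])


def _height_map(values, ground=1.05):
    return ha.HeightMap(values, np.isfinite(values), ground)


class TestSampleRois:
    def test_large_leaf_packs_at_least_nine_size30_squares(self, sim_rig):
        h = np.full((120, 120), np.nan)
        h[10:100, 10:100] = 0.2
        hmap = _height_map(h)
        plant = np.isfinite(h)
        rois = lf.sample_rois(hmap, np.zeros_like(plant), plant, sim_rig,
                              min_count=5)
        assert len(rois) >= 9
        assert all(r.size == 30 for r in rois)

    def test_edge_lattice_forces_fallback_to_size10(self, sim_rig):
        h = np.full((120, 120), 0.2)
        edges = np.zeros((120, 120), bool)
        edges[::15, :] = True    # 15 px lattice blocks 30 and 20 px squares
        edges[:, ::15] = True
        plant = np.ones_like(edges)
        rois = lf.sample_rois(_height_map(h), edges, plant, sim_rig,
                              min_count=10)
        assert rois
        assert all(r.size == 10 for r in rois)

    def test_all_soil_mask_yields_empty_list(self, sim_rig):
        h = np.full((60, 60), 0.2)
        rois = lf.sample_rois(_height_map(h), np.zeros((60, 60), bool),
                              np.zeros((60, 60), bool), sim_rig)
        assert rois == []

    def test_rois_never_overlap_and_never_contain_edges(self, sim_rig):
        rng = np.random.default_rng(0)
        h = np.where(rng.random((150, 150)) > 0.1, 0.25, np.nan)
        edges = rng.random((150, 150)) > 0.97
        plant = np.isfinite(h)
        rois = lf.sample_rois(_height_map(h), edges, plant, sim_rig, min_count=3)
        boxes = []
        for r in rois:
            r0, c0 = r.origin
            assert not edges[r0:r0 + r.size, c0:c0 + r.size].any()
            assert plant[r0:r0 + r.size, c0:c0 + r.size].all()
            boxes.append((r0, c0, r.size))
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                r0, c0, s0 = boxes[i]
                r1, c1, s1 = boxes[j]
                assert (r0 + s0 <= r1 or r1 + s1 <= r0
                        or c0 + s0 <= c1 or c1 + s1 <= c0)

    def test_implausible_heights_block_a_square(self, sim_rig):
        h = np.full((40, 40), 0.2)
        h[5, 5] = 0.9   # above the plausible band for ground at 1.05
        rois = lf.sample_rois(_height_map(h), np.zeros((40, 40), bool),
                              np.ones((40, 40), bool), sim_rig, min_count=1,
                              sizes=(30,))
        assert all(r.origin != (0, 0) for r in rois)


class TestLadHistogram:
    def _roi(self, tilt):
        return lf.LeafROI(origin=(0, 0), size=10, tilt=tilt, fit_rms=0.0)

    def test_single_angle_fills_one_bin(self):
        lad = lf.lad_histogram([self._roi(47.0)] * 5)
        assert lad.frequencies[9] == pytest.approx(1.0)   # [45, 50)
        assert lad.frequencies.sum() == pytest.approx(1.0)

    def test_uniform_angles_fill_bins_evenly(self):
        rng = np.random.default_rng(0)
        rois = [self._roi(t) for t in rng.uniform(0, 90, 4000)]
        lad = lf.lad_histogram(rois)
        assert np.max(np.abs(lad.frequencies - 1 / 18)) < 0.02

    def test_frequencies_always_sum_to_one(self):
        rng = np.random.default_rng(1)
        for n in (1, 7, 123):
            rois = [self._roi(t) for t in rng.uniform(0, 90, n)]
            assert lf.lad_histogram(rois).frequencies.sum() == pytest.approx(1.0)

    def test_mean_tilt_invariant_to_roi_order(self):
        rng = np.random.default_rng(2)
        tilts = rng.uniform(0, 90, 50)
        fwd = lf.lad_histogram([self._roi(t) for t in tilts])
        rev = lf.lad_histogram([self._roi(t) for t in tilts[::-1]])
        assert fwd.mean_tilt == pytest.approx(rev.mean_tilt)
        np.testing.assert_allclose(fwd.frequencies, rev.frequencies)

    def test_empty_roi_list_is_nan_sentinel(self):
        lad = lf.lad_histogram([])
        assert lad.n_rois == 0
        assert np.isnan(lad.mean_tilt)

    def test_recovered_distribution_matches_generator(self, sim_rig):
        """ROI tilts sampled from noisy planar leaves reproduce the generating
        tilt distribution with small total variation."""
        rng = np.random.default_rng(3)
        tilts = np.clip(rng.normal(40, 12, 220), 2, 80)
        rois = []
        for i, t in enumerate(tilts):
            x = rng.uniform(-0.015, 0.015, 300)
            y = rng.uniform(-0.015, 0.015, 300)
            z = np.tan(np.radians(t)) * x + rng.normal(0, 3e-4, 300)
            normal, _ = lf.fit_plane(np.column_stack([x, y, z]))
            rois.append(lf.LeafROI((0, 0), 10, lf.tilt_from_normal(normal), 0.0))
        lad = lf.lad_histogram(rois)
        edges = lad.bin_edges
        truth, _ = np.histogram(np.clip(tilts, 0, 90 - 1e-9), bins=edges)
        tv = 0.5 * np.abs(lad.frequencies - truth / truth.sum()).sum()
        assert tv < 0.15


class TestLocalVersusDelaunayOnFlatTargets:
    def test_local_fitting_beats_delaunay_for_shallow_tilts(self, sim_rig):
        """For noisy nearly-flat targets the unsigned face tilts of the mesh
        cannot cancel, so local plane fitting lands closer to the truth."""
        from canostereo import mesh_traits as mt

        rng = np.random.default_rng(5)
        tilt = 8.0
        n, s = 120, 0.0011
        x, y = np.meshgrid(np.arange(n) * s, np.arange(n) * s)
        z = 0.9 + np.tan(np.radians(tilt)) * x + rng.normal(0, 0.002, (n, n))
        dmap = cg.DepthMap(z, np.ones_like(z, bool))
        md, _ = mt.prepare_depth_for_mesh(dmap, 1, 5)
        mesh = mt.build_mesh(mt.grid_point_cloud(x, y, md.values))
        err_delaunay = abs(mt.compute_mta_delaunay(mesh) - tilt)

        hmap = ha.HeightMap(1.05 - z, np.ones_like(z, bool), 1.05)
        rois = lf.sample_rois(hmap, np.zeros_like(z, bool),
                              np.ones_like(z, bool), sim_rig, min_count=5)
        lad = lf.lad_histogram(rois)
        err_local = abs(lad.mean_tilt - tilt)
        assert err_local < err_delaunay
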