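"""Canopy meshing, face formulas, LAI/MTA and depth conditioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import canostereo as cs
from canostereo import camera_geometry as cg
from canostereo import mesh_traits as mt


def _grid_cloud(n, spacing=1.0, z=None):
    x, y = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    if z is None:
        z = np.zeros_like(x)
    return mt.grid_point_cloud(x, y, z)


class TestFaceFormulas:
    def test_unit_right_triangle_area(self):
        assert mt.face_area((0, 0, 0), (1, 0, 0), (0, 1, 0)) == pytest.approx(0.5)

    def test_area_symmetric_under_relabeling(self):
        a, b, c = (0.3, 0.1, 2.0), (1.2, 0.4, 1.1), (0.7, 1.5, 0.2)
        areas = {mt.face_area(*perm) for perm in
                 [(a, b, c), (b, c, a), (c, a, b), (a, c, b)]}
        assert max(areas) - min(areas) < 1e-14

    def test_degenerate_face_has_zero_area_and_nan_tilt(self):
        assert mt.face_area((0, 0, 0), (1, 1, 1), (2, 2, 2)) == 0.0
        assert np.isnan(mt.face_tilt((0, 0, 0), (1, 1, 1), (2, 2, 2)))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=9, max_size=9))
    def test_area_agrees_with_herons_formula(self, coords):
        a, b, c = np.array(coords).reshape(3, 3)
        la, lb, lc = (np.linalg.norm(b - c), np.linalg.norm(a - c),
                      np.linalg.norm(a - b))
        s = (la + lb + lc) / 2
        heron_sq = max(s * (s - la) * (s - lb) * (s - lc), 0.0)
        heron = np.sqrt(heron_sq)
        got = mt.face_area(a, b, c)
        assert got == pytest.approx(heron, rel=1e-9, abs=1e-9)

    def test_horizontal_face_tilt_zero(self):
        assert mt.face_tilt((0, 0, 1), (1, 0, 1), (0, 1, 1)) == pytest.approx(0.0)

    def test_vertical_face_tilt_ninety(self):
        assert mt.face_tilt((0, 0, 0), (1, 0, 0), (0, 0, 1)) == pytest.approx(90.0)

    @pytest.mark.parametrize("angle", [10.0, 30.0, 55.0, 80.0])
    def test_rotated_horizontal_face_recovers_rotation_angle(self, angle):
        th = np.radians(angle)
        R = np.array([[1, 0, 0],
                      [0, np.cos(th), -np.sin(th)],
                      [0, np.sin(th), np.cos(th)]])
        tri = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]) @ R.T
        assert mt.face_tilt(*tri) == pytest.approx(angle, abs=1e-9)


class TestBuildMesh:
    def test_two_by_two_block_gives_two_faces(self):
        mesh = mt.build_mesh(_grid_cloud(2))
        assert mesh.n_faces == 2
        assert mesh.total_area == pytest.approx(1.0)

    def test_planar_grid_total_area_is_exact(self):
        k = 15
        mesh = mt.build_mesh(_grid_cloud(k, spacing=0.01))
        assert mesh.total_area == pytest.approx(((k - 1) * 0.01) ** 2, rel=1e-9)

    def test_euler_bound_on_face_count(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 50, (200, 2))
        cloud = mt.PointCloud(points=np.column_stack([pts, np.zeros(200)]),
                              pixel_index=pts[:, ::-1])
        mesh = mt.build_mesh(cloud)
        assert mesh.n_faces <= 2 * 200

    def test_too_few_points_rejected(self):
        cloud = mt.PointCloud(points=np.zeros((2, 3)), pixel_index=np.zeros((2, 2)))
        with pytest.raises(mt.MeshError):
            mt.build_mesh(cloud)

    def test_collinear_points_rejected(self):
        pix = np.column_stack([np.zeros(5), np.arange(5)])
        cloud = mt.PointCloud(points=np.column_stack([pix, np.zeros(5)]),
                              pixel_index=pix)
        with pytest.raises(mt.MeshError):
            mt.build_mesh(cloud)


class TestGiantTriangleFilter:
    def test_faces_never_span_two_separated_leaves(self):
        # two parallel 'leaves' 0.2 m apart in depth, adjacent in the image
        x, y = np.meshgrid(np.arange(10) * 0.002, np.arange(5) * 0.002)
        z_near = np.full_like(x, 0.8)
        z_far = np.full_like(x, 1.0)
        z = np.vstack([z_near, z_far])
        cloud = mt.grid_point_cloud(np.vstack([x, x]), np.vstack([y, y + 0.01]), z)
        mesh = mt.filter_giant_triangles(mt.build_mesh(cloud), max_edge=0.05)
        face_z = mesh.vertices[mesh.faces][:, :, 2]
        spans = face_z.max(axis=1) - face_z.min(axis=1)
        assert mesh.n_faces > 0
        assert np.all(spans < 0.1)

    def test_infinite_threshold_is_identity(self):
        mesh = mt.build_mesh(_grid_cloud(5))
        out = mt.filter_giant_triangles(mesh, max_edge=np.inf)
        assert out.n_faces == mesh.n_faces

    def test_threshold_below_spacing_removes_everything(self):
        mesh = mt.build_mesh(_grid_cloud(5, spacing=1.0))
        assert mt.filter_giant_triangles(mesh, max_edge=0.5).n_faces == 0


class TestTraits:
    def test_lai_of_empty_mesh_is_zero(self):
        mesh = mt.filter_giant_triangles(mt.build_mesh(_grid_cloud(3)), 0.1)
        assert mt.compute_lai(mesh, 0.5) == 0.0

    def test_lai_is_area_over_footprint(self):
        mesh = mt.build_mesh(_grid_cloud(11, spacing=0.01))  # 0.01 m^2 patch
        assert mt.compute_lai(mesh, 0.5) == pytest.approx(0.02, rel=1e-9)

    def test_lai_rejects_zero_soil_area(self):
        mesh = mt.build_mesh(_grid_cloud(3))
        with pytest.raises(ValueError):
            mt.compute_lai(mesh, 0.0)

    def test_mta_of_constant_tilt_plane(self):
        z = np.tan(np.radians(45.0)) * np.arange(12)[None, :] * np.ones((12, 1))
        mesh = mt.build_mesh(_grid_cloud(12, z=z))
        assert mt.compute_mta_delaunay(mesh) == pytest.approx(45.0, abs=1e-9)

    def test_mta_averages_mixed_tilts(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0],     # horizontal: 0 deg
                      [3, 0, 0], [4, 0, 0], [3, 0, 1]])     # vertical: 90 deg
        mesh = mt.CanopyMesh(vertices=v, faces=np.array([[0, 1, 2], [3, 4, 5]]))
        assert mt.compute_mta_delaunay(mesh) == pytest.approx(45.0)

    def test_mta_of_empty_mesh_is_nan(self):
        mesh = mt.filter_giant_triangles(mt.build_mesh(_grid_cloud(3)), 0.1)
        assert np.isnan(mt.compute_mta_delaunay(mesh))

    def test_lai_invariant_under_lateral_translation(self):
        rng = np.random.default_rng(1)
        z = 0.9 + 0.01 * rng.standard_normal((10, 10))
        x, y = np.meshgrid(np.arange(10) * 0.002, np.arange(10) * 0.002)
        m1 = mt.build_mesh(mt.grid_point_cloud(x, y, z))
        m2 = mt.build_mesh(mt.grid_point_cloud(x + 0.3, y - 0.2, z))
        assert m2.total_area == pytest.approx(m1.total_area, rel=1e-12)


class TestDepthConditioning:
    def _dmap(self, vals, valid=None):
        if valid is None:
            valid = np.isfinite(vals)
        return cg.DepthMap(vals, valid)

    def test_median_constant_field_unchanged(self):
        d = self._dmap(np.full((9, 9), 0.9))
        out = mt.median_filter_depth(d, 5)
        np.testing.assert_allclose(out.values, 0.9)

    def test_median_removes_single_spike(self):
        vals = np.full((9, 9), 0.9)
        vals[4, 4] = 0.5
        out = mt.median_filter_depth(self._dmap(vals), 5)
        assert out.values[4, 4] == pytest.approx(0.9)

    def test_median_rejects_even_window(self):
        with pytest.raises(ValueError):
            mt.median_filter_depth(self._dmap(np.full((6, 6), 1.0)), 4)

    def test_median_preserves_invalid_cells(self):
        vals = np.full((9, 9), 0.9)
        valid = np.ones((9, 9), bool)
        valid[2, 3] = False
        vals[2, 3] = np.nan
        out = mt.median_filter_depth(cg.DepthMap(vals, valid), 5)
        assert not out.valid[2, 3]

    def test_median_reduces_staircase_deviation(self):
        """Quantized tilted plane with random depth error: the 5x5 median
        brings depths closer to the true plane (the stair-step regime combines
        resolution quantization and random matching error)."""
        rng = np.random.default_rng(0)
        n = 60
        true = 0.9 + 0.0006 * np.arange(n)[None, :] * np.ones((n, 1))
        step = 0.002
        noisy = true + rng.normal(0, step / 2, true.shape)
        quant = np.round(noisy / step) * step
        out = mt.median_filter_depth(self._dmap(quant.copy()), 5)
        before = np.abs(quant - true)[:, 5:-5].mean()
        after = np.abs(out.values - true)[:, 5:-5].mean()
        assert after < before

    def test_bin_depth_averages_valid_neighbors(self):
        vals = np.full((8, 8), 1.0)
        vals[0, 0] = 1.2
        out = mt.bin_depth(self._dmap(vals), 4)
        assert out.values.shape == (2, 2)
        assert out.values[0, 0] == pytest.approx((15 * 1.0 + 1.2) / 16)

    def test_bin_depth_requires_half_valid(self):
        vals = np.full((4, 4), 1.0)
        valid = np.zeros((4, 4), bool)
        valid[0, 0] = True  # 1 of 16 valid
        vals[~valid] = np.nan
        out = mt.bin_depth(cg.DepthMap(vals, valid), 4)
        assert not out.valid[0, 0]


class TestStairStepInvariants:
    def _quantized_plane_mesh(self, tilt_deg, n=80, bin_factor=1, median=0):
        # orthographic height field: lateral spacing s, depths quantized to s
        s = 1.0
        x, y = np.meshgrid(np.arange(n) * s, np.arange(n) * s)
        z = np.tan(np.radians(tilt_deg)) * x
        zq = np.round(z / s) * s
        dmap = cg.DepthMap(zq + 10.0, np.ones_like(zq, bool))
        if bin_factor > 1 or median:
            dmap, _ = mt.prepare_depth_for_mesh(dmap, bin_factor, median)
            f = bin_factor
            x = x[: dmap.values.shape[0] * f: f, : dmap.values.shape[1] * f: f]
            y = y[: dmap.values.shape[0] * f: f, : dmap.values.shape[1] * f: f]
        return mt.build_mesh(mt.grid_point_cloud(x, y, dmap.values - 10.0))

    def test_nonhorizontal_faces_are_at_least_45_degrees(self):
        mesh = self._quantized_plane_mesh(20.0)
        nh = mesh.face_tilt[mesh.face_tilt > 1e-9]
        assert nh.size > 0
        assert nh.min() >= 45.0 - 1e-9

    def test_quantized_plane_area_is_overestimated(self):
        n = 80
        mesh = self._quantized_plane_mesh(20.0, n=n)
        true_area = (n - 1) ** 2 / np.cos(np.radians(20.0))
        assert mesh.total_area >= true_area

    def test_area_bias_shrinks_under_median_and_binning(self, sim_rig):
        """Qualitative lab-table ordering: a 5x5 depth median and a 2x binning
        each reduce the stair-step area overestimation of a tilted target."""
        leaf = cs.LeafQuad(center=np.array([0.0, 0.0, 0.9]), width=0.3,
                           length=0.25, tilt=20.0, azimuth=0.0)
        scene = cs.SceneSpec(rig=sim_rig, ground_depth=1.05, leaves=[leaf], seed=2)
        dmap, labels = scene.true_depth_left()
        plant = labels == cs.LEAF
        step = float(cs.depth_resolution(0.9, sim_rig))
        quant = cs.quantize_depth(
            cg.DepthMap(np.where(plant, dmap.values, np.nan), plant), step)

        def area(bin_factor, median):
            md, _ = mt.prepare_depth_for_mesh(quant, bin_factor, median)
            rig2 = mt.scaled_rig_for_binning(sim_rig, bin_factor)
            mesh = mt.filter_giant_triangles(
                mt.build_mesh(mt.depth_map_to_point_cloud(md, rig2)), 0.05)
            return mesh.total_area

        raw, med5, binned = area(1, 0), area(1, 5), area(2, 0)
        assert raw > leaf.area          # stair-step inflates
        assert med5 < raw               # median reduces the inflation
        assert binned < raw             # so does 2x binning

    def test_tilted_plane_mta_less_biased_than_horizontal_under_noise(self, sim_rig):
        """Unsigned tilts cannot cancel on a flat target, so at equal noise the
        horizontal plane's MTA error exceeds a 30-degree plane's."""
        rng = np.random.default_rng(4)
        n, s = 90, 0.001
        x, y = np.meshgrid(np.arange(n) * s, np.arange(n) * s)
        noise = rng.normal(0, 0.0008, (n, n))

        def mta_err(tilt):
            z = 0.9 + np.tan(np.radians(tilt)) * x + noise
            dmap = cg.DepthMap(z, np.ones_like(z, bool))
            md, _ = mt.prepare_depth_for_mesh(dmap, 1, 5)
            mesh = mt.build_mesh(mt.grid_point_cloud(x, y, md.values))
            return abs(mt.compute_mta_delaunay(mesh) - tilt)

        assert mta_err(30.0) < mta_err(0.0)
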