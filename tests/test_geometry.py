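"""Projection geometry and triangulation: exact identities and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mvkvtrack.geometry import (
    DegenerateProjectionError,
    DetectorBoundsError,
    DetectorPoint,
    GeometryError,
    IllConditionedGeometryError,
    ImagingGeometry,
    PatientPoint,
    detector_to_pixel,
    kv_angle_for,
    pixel_to_detector,
    project,
    project_many,
    rotation_matrix,
    triangulate,
)

ANGLES = st.floats(min_value=-720, max_value=720, allow_nan=False)


class TestRotationMatrix:
    def test_zero_rotation_is_identity(self):
        assert np.allclose(rotation_matrix(0.0), np.eye(3))

    @settings(max_examples=30, derandomize=True)
    @given(theta=ANGLES)
    def test_orthonormal(self, theta):
        r = rotation_matrix(theta)
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)
        assert np.isclose(np.linalg.det(r), 1.0)

    def test_inverse_composition(self):
        v = np.array([1.3, -0.7, 2.2])
        out = rotation_matrix(-90.0) @ (rotation_matrix(90.0) @ v)
        assert np.allclose(out, v, atol=1e-12)

    @pytest.mark.parametrize("theta", [13.0, 222.5])
    def test_specific_angles_orthonormal(self, theta):
        r = rotation_matrix(theta)
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)

    def test_rotates_about_longitudinal_axis(self):
        # z (superior-inferior) is invariant under gantry rotation
        v = rotation_matrix(123.4) @ np.array([0.0, 0.0, 5.0])
        assert np.allclose(v, [0.0, 0.0, 5.0])


class TestImagingGeometry:
    def test_distance_invariant_enforced(self):
        with pytest.raises(GeometryError):
            ImagingGeometry(system_label="MV", gantry_angle_deg=0.0, sid_mm=1400.0)

    def test_defaults_match_reference_setup(self, mv_geom, kv_geom):
        assert mv_geom.sad_mm == 1000.0 and mv_geom.sid_mm == 1500.0
        assert mv_geom.idd_mm == 500.0
        assert mv_geom.pixel_pitch_mm == 0.392
        assert kv_geom.pixel_pitch_mm == 0.388

    def test_kv_trails_mv_by_90(self):
        assert kv_angle_for(40.0) == -50.0


class TestProject:
    def test_isocenter_projects_to_detector_center(self):
        for ang in (0.0, 37.0, 180.0, 271.5):
            d = project(ImagingGeometry.mv(ang), PatientPoint(0, 0, 0))
            assert d.i_mm == 0.0 and d.k_mm == 0.0

    def test_isocenter_plane_magnification(self, mv_geom):
        # 10 mm perpendicular offset in the isocenter plane magnifies by SID/SAD
        d = project(mv_geom, PatientPoint(10.0, 0.0, 0.0))
        assert np.isclose(d.i_mm, 15.0) and np.isclose(d.k_mm, 0.0)

    @settings(max_examples=30, derandomize=True)
    @given(theta=ANGLES, x=st.floats(-30, 30), y=st.floats(-30, 30), z=st.floats(-30, 30))
    def test_magnification_factor_exact(self, theta, x, y, z):
        # any point in the isocenter plane (system-frame y = 0) magnifies
        # exactly by SID/SAD
        geom = ImagingGeometry.mv(theta)
        p_sys = np.array([x, 0.0, z])
        p_pat = rotation_matrix(theta).T @ p_sys
        d = project(geom, PatientPoint.from_array(p_pat))
        assert np.isclose(d.i_mm, x * 1.5, atol=1e-9)
        assert np.isclose(d.k_mm, z * 1.5, atol=1e-9)

    def test_collinearity_along_ray(self, mv_geom):
        # midpoint of source and point projects to the same detector position
        p = np.array([7.0, -12.0, 3.0])
        source = np.array([0.0, mv_geom.sad_mm, 0.0])  # theta = 0: system = patient
        mid = (p + source) / 2.0
        d1 = project(mv_geom, PatientPoint.from_array(p))
        d2 = project(mv_geom, PatientPoint.from_array(mid))
        assert np.isclose(d1.i_mm, d2.i_mm, atol=1e-9)
        assert np.isclose(d1.k_mm, d2.k_mm, atol=1e-9)

    def test_point_behind_source_raises(self, mv_geom):
        with pytest.raises(DegenerateProjectionError):
            project(mv_geom, PatientPoint(0.0, 1100.0, 0.0))

    def test_frame_equivariance(self):
        # rotating both geometry and point together leaves (i, k) unchanged
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(-25, 25, 3)
            theta = float(rng.uniform(0, 360))
            extra = float(rng.uniform(0, 360))
            d0 = project(ImagingGeometry.mv(theta), PatientPoint.from_array(p))
            p_rot = rotation_matrix(extra).T @ p
            d1 = project(ImagingGeometry.mv(theta + extra), PatientPoint.from_array(p_rot))
            assert np.isclose(d0.i_mm, d1.i_mm, atol=1e-9)
            assert np.isclose(d0.k_mm, d1.k_mm, atol=1e-9)


class TestTriangulate:
    def test_projection_triangulation_consistency(self):
        p = PatientPoint(3.0, -2.0, 7.5)
        g_mv = ImagingGeometry.mv(40.0)
        g_kv = ImagingGeometry.kv(310.0)
        tri = triangulate(project(g_kv, p), project(g_mv, p), g_kv, g_mv)
        assert np.allclose(tri.point.as_array(), p.as_array(), atol=1e-6)
        assert tri.residual_mm < 1e-9

    def test_isocenter_point_recovers_origin(self):
        g_mv, g_kv = ImagingGeometry.mv(10.0), ImagingGeometry.kv(-80.0)
        tri = triangulate(DetectorPoint(0, 0), DetectorPoint(0, 0), g_kv, g_mv)
        assert np.allclose(tri.point.as_array(), 0.0, atol=1e-9)
        assert tri.residual_mm < 1e-9

    def test_identity_over_random_points(self):
        # project -> triangulate recovers 1000 random points to < 1e-6 mm
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(1000):
            p = PatientPoint.from_array(rng.uniform(-30, 30, 3))
            th_mv = float(rng.uniform(0, 360))
            sep = float(rng.uniform(10, 170)) * (1 if rng.random() < 0.5 else -1)
            g_mv = ImagingGeometry.mv(th_mv)
            g_kv = ImagingGeometry.kv(th_mv + sep)
            tri = triangulate(project(g_kv, p), project(g_mv, p), g_kv, g_mv)
            worst = max(worst, float(np.max(np.abs(tri.point.as_array() - p.as_array()))))
        assert worst < 1e-6

    def test_near_parallel_geometry_rejected(self):
        g_mv = ImagingGeometry.mv(0.0)
        for kv_angle in (3.0, 183.0):  # < 5 deg separation mod 180
            g_kv = ImagingGeometry.kv(kv_angle)
            with pytest.raises(IllConditionedGeometryError):
                triangulate(DetectorPoint(1, 1), DetectorPoint(1, 1), g_kv, g_mv)

    def test_matches_brute_force_grid_oracle(self):
        # independent oracle: coarse-to-fine 3-D grid search minimising the
        # summed squared reprojection error, final grid step 0.01 mm
        rng = np.random.default_rng(3)

        def reproj_sq_error(cands, obs_list, geoms):
            err = np.zeros(len(cands))
            for obs, geom in zip(obs_list, geoms):
                ik = project_many(geom, cands)
                err += (ik[:, 0] - obs.i_mm) ** 2 + (ik[:, 1] - obs.k_mm) ** 2
            return err

        def oracle(obs_list, geoms):
            center = np.zeros(3)
            for half, step in ((30.0, 1.0), (1.5, 0.1), (0.15, 0.01)):
                ax = np.arange(-half, half + step / 2, step)
                gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
                cands = center + np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
                err = reproj_sq_error(cands, obs_list, geoms)
                center = cands[int(np.argmin(err))]
            return center

        for _ in range(20):
            p = rng.uniform(-20, 20, 3)
            th = float(rng.uniform(0, 360))
            g_mv = ImagingGeometry.mv(th)
            g_kv = ImagingGeometry.kv(th + float(rng.uniform(45, 135)))
            # perturbed observations: least-squares point is non-trivial
            kv_obs = project(g_kv, PatientPoint.from_array(p))
            mv_obs = project(g_mv, PatientPoint.from_array(p))
            kv_obs = DetectorPoint(kv_obs.i_mm + rng.uniform(-0.05, 0.05),
                                   kv_obs.k_mm + rng.uniform(-0.05, 0.05))
            mv_obs = DetectorPoint(mv_obs.i_mm + rng.uniform(-0.05, 0.05),
                                   mv_obs.k_mm + rng.uniform(-0.05, 0.05))
            tri = triangulate(kv_obs, mv_obs, g_kv, g_mv)
            ref = oracle([kv_obs, mv_obs], [g_kv, g_mv])
            assert np.all(np.abs(tri.point.as_array() - ref) <= 0.011)

    def test_two_degree_angle_error_displacement_bound(self):
        # three fiducials, COM at isocenter: a +2 deg MV angle mis-assignment
        # perturbs the recovered 3-D displacement by < 0.05 mm
        from mvkvtrack.simulate import default_fiducials

        fids = default_fiducials()
        com = np.mean([f.center.as_array() for f in fids], axis=0)
        assert np.allclose(com, 0.0)
        for th in (0.0, 55.0, 140.0, 260.0):
            g_mv_true = ImagingGeometry.mv(th)
            g_kv = ImagingGeometry.kv(th - 90.0)
            g_mv_mis = ImagingGeometry.mv(th + 2.0)
            # observed detector COM = mean of the projected fiducial centers
            mv_com = np.mean(
                [project_many(g_mv_true, f.center.as_array()[None])[0] for f in fids],
                axis=0,
            )
            kv_com = np.mean(
                [project_many(g_kv, f.center.as_array()[None])[0] for f in fids],
                axis=0,
            )
            tri = triangulate(
                DetectorPoint(*kv_com), DetectorPoint(*mv_com), g_kv, g_mv_mis
            )
            # true displacement is zero; the recovered point is the error
            assert np.linalg.norm(tri.point.as_array()) < 0.05


class TestPixelConversion:
    def test_center_pixel_maps_to_origin(self, mv_geom):
        rows = mv_geom.detector_px[1]
        cols = mv_geom.detector_px[0]
        d = pixel_to_detector(((rows - 1) / 2, (cols - 1) / 2), mv_geom)
        assert d.i_mm == 0.0 and d.k_mm == 0.0

    def test_one_column_right_is_plus_one_pitch(self, mv_geom):
        rows, cols = mv_geom.detector_px[1], mv_geom.detector_px[0]
        d = pixel_to_detector(((rows - 1) / 2, (cols - 1) / 2 + 1), mv_geom)
        assert np.isclose(d.i_mm, 0.392)

    def test_roundtrip_on_toy_detector(self):
        geom = ImagingGeometry.mv(0.0, detector_px=(16, 16))
        for r in range(16):
            for c in range(16):
                d = pixel_to_detector((r, c), geom)
                rr, cc = detector_to_pixel(d, geom)
                assert np.isclose(rr, r, atol=1e-12) and np.isclose(cc, c, atol=1e-12)

    def test_out_of_detector_raises(self, mv_geom):
        with pytest.raises(DetectorBoundsError):
            pixel_to_detector((-5.0, 10.0), mv_geom)
        with pytest.raises(DetectorBoundsError):
            detector_to_pixel(DetectorPoint(1e4, 0.0), mv_geom)
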