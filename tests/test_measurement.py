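import numpy as np
import pytest
import trimesh

from bunchmetric.errors import AlphaTooSmallError, ArgumentError, DegenerateGeometryError
from bunchmetric.geometry import PointCloud, RigidTransform, mesh_volume
from bunchmetric.measurement import (
    AlphaShapeParams,
    MeasureConfig,
    SizeTriple,
    measure_all,
    size_extent,
    volume_alpha_shape,
    volume_convex_hull,
    volume_gm,
    volume_pb,
    volume_voxel,
)
from bunchmetric.poisson import PoissonParams, reconstruct_poisson

from conftest import ball_points, sphere_cloud

SPHERE_VOL = 4.0 / 3.0 * np.pi * 125.0  # r = 5 cm


def box_lattice(lx, ly, lz, pitch=0.5):
    ax = [np.arange(0, L + pitch / 2, pitch) for L in (lx, ly, lz)]
    g = np.meshgrid(*ax)
    return np.array(g).reshape(3, -1).T


class TestSizeExtent:
    def test_axis_aligned_box(self):
        size = size_extent(PointCloud(box_lattice(10, 8, 20)))
        assert sorted([size.l, size.w, size.h]) == pytest.approx([8, 10, 20], rel=1e-6)
        assert size.h == pytest.approx(20, rel=1e-6)  # largest-variance axis
        assert size.l >= size.w

    def test_rotation_invariance(self, rng):
        pts = box_lattice(10, 8, 20)
        pts += 0.01 * rng.normal(size=pts.shape)  # break lattice symmetry ties
        s0 = size_extent(PointCloud(pts))
        T = RigidTransform.about_y(37.0)
        s1 = size_extent(PointCloud(T.apply(pts)))
        for a, b in zip((s0.l, s0.w, s0.h), (s1.l, s1.w, s1.h)):
            assert a == pytest.approx(b, rel=0.01)

    def test_sphere_extents(self):
        size = size_extent(sphere_cloud(20000))
        for v in (size.l, size.w, size.h):
            assert v == pytest.approx(10.0, rel=0.02)

    def test_lab_frame(self):
        size = size_extent(PointCloud(box_lattice(10, 20, 8)), frame="lab")
        assert size.h == pytest.approx(20, rel=1e-6)  # lab vertical is Y


class TestGM:
    def test_formula(self):
        assert volume_gm(SizeTriple(10, 8, 12)) == pytest.approx(np.pi * 25 * 12)

    def test_exact_cylinder(self):
        assert volume_gm(SizeTriple(4, 4, 7)) == pytest.approx(np.pi * 4 * 7)

    def test_overestimates_sphere(self):
        size = size_extent(sphere_cloud(20000))
        gm = volume_gm(size)
        assert gm > 1.4 * SPHERE_VOL  # cylinder over sphere: factor 1.5


class TestConvexHull:
    def test_unit_cube_corners(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                           dtype=float)
        mesh, vol = volume_convex_hull(PointCloud(corners))
        assert vol == pytest.approx(1.0, abs=1e-9)
        assert mesh.is_watertight

    def test_dense_sphere_close_to_analytic(self):
        mesh, vol = volume_convex_hull(sphere_cloud(8000))
        assert vol <= SPHERE_VOL  # inscribed polyhedron
        assert vol == pytest.approx(SPHERE_VOL, rel=0.01)
        # cross-check against an independent implementation
        tm = trimesh.convex.convex_hull(sphere_cloud(8000).points)
        assert vol == pytest.approx(tm.volume, rel=1e-6)

    def test_coplanar_rejected(self, rng):
        pts = np.column_stack([rng.normal(size=(100, 2)), np.zeros(100)])
        with pytest.raises(DegenerateGeometryError):
            volume_convex_hull(PointCloud(pts))


class TestAlphaShape:
    def test_regular_tetrahedron_analytic(self):
        v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
        v /= np.linalg.norm(v[0] - v[1])  # edge length 1
        _, vol = volume_alpha_shape(PointCloud(v), AlphaShapeParams(alpha=0.62))
        assert vol == pytest.approx(1.0 / (6 * np.sqrt(2)), rel=1e-9)

    def test_alpha_infinity_equals_hull(self, rng):
        cloud = PointCloud(rng.normal(size=(500, 3)) * [3, 2, 1])
        _, hull_vol = volume_convex_hull(cloud)
        _, as_vol = volume_alpha_shape(cloud, AlphaShapeParams(alpha=1e9))
        assert as_vol == pytest.approx(hull_vol, rel=1e-6)

    def test_two_separated_spheres(self):
        a = ball_points(60000, radius=5.0, seed=1)
        b = ball_points(60000, radius=5.0, seed=2) + np.array([20.0, 0, 0])
        cloud = PointCloud(np.vstack([a, b]))
        _, vol = volume_alpha_shape(cloud, AlphaShapeParams(alpha=1.5))
        assert vol == pytest.approx(2 * SPHERE_VOL, rel=0.05)

    def test_alpha_monotonicity_and_hull_bound(self, rng):
        cloud = PointCloud(rng.normal(size=(400, 3)) * [3, 2, 1])
        _, v1 = volume_alpha_shape(cloud, AlphaShapeParams(alpha=1.0))
        _, v2 = volume_alpha_shape(cloud, AlphaShapeParams(alpha=2.0))
        _, hull = volume_convex_hull(cloud)
        assert v1 <= v2 + 1e-6 <= hull + 1e-6

    def test_alpha_too_small(self, rng):
        cloud = PointCloud(rng.uniform(0, 100, (50, 3)))
        with pytest.raises(AlphaTooSmallError):
            volume_alpha_shape(cloud, AlphaShapeParams(alpha=0.001))


class TestVoxelVolume:
    def test_single_point(self):
        assert volume_voxel(PointCloud([[0.3, 0.3, 0.3]]), 2.0) == pytest.approx(8.0)

    def test_solid_sphere_convergence(self):
        cloud = PointCloud(ball_points(400_000, radius=5.0, seed=0))
        err = {e: abs(volume_voxel(cloud, e) - SPHERE_VOL) / SPHERE_VOL
               for e in (0.5, 0.25)}
        assert err[0.5] < 0.2
        assert err[0.25] < 0.6 * err[0.5]

    def test_shell_much_smaller_than_solid(self):
        shell = volume_voxel(sphere_cloud(20000), 0.5)
        solid = volume_voxel(PointCloud(ball_points(200_000, seed=3)), 0.5)
        assert shell < 0.4 * solid  # occupancy measures the sampled shell only


class TestPoisson:
    def test_sphere_volume_and_watertight(self):
        mesh, vol = volume_pb(sphere_cloud(8000), PoissonParams(grid_resolution=96))
        assert mesh.is_watertight
        assert vol == pytest.approx(SPHERE_VOL, rel=0.05)

    def test_inward_normals_auto_flipped(self):
        cloud = sphere_cloud(6000)
        flipped = PointCloud(cloud.points, -cloud.normals)
        _, vol = volume_pb(flipped, PoissonParams(grid_resolution=96))
        assert vol == pytest.approx(SPHERE_VOL, rel=0.05)

    def test_torus_genus_preserved(self):
        t = trimesh.creation.torus(major_radius=5, minor_radius=2,
                                   major_sections=64, minor_sections=32)
        pts, fidx = trimesh.sample.sample_surface(t, 12000, seed=0)
        cloud = PointCloud(np.array(pts), t.face_normals[fidx])
        mesh = reconstruct_poisson(cloud, PoissonParams(grid_resolution=96))
        assert mesh.is_watertight
        assert mesh.euler_characteristic() == 0

    def test_hole_robustness(self):
        cloud = sphere_cloud(9000)
        keep = cloud.points[:, 2] < 4.0  # delete a cap (~20% of the area)
        holed = cloud.select(keep)
        mesh = reconstruct_poisson(holed, PoissonParams(grid_resolution=96))
        assert mesh.is_watertight
        assert mesh_volume(mesh) == pytest.approx(SPHERE_VOL, rel=0.08)

    def test_requires_normals(self):
        with pytest.raises(ArgumentError):
            reconstruct_poisson(sphere_cloud(100, normals=False))

    def test_rigid_invariance_within_grid_tolerance(self):
        cloud = sphere_cloud(6000)
        _, v0 = volume_pb(cloud, PoissonParams(grid_resolution=96))
        T = RigidTransform.about_y(30.0)
        moved = PointCloud(T.apply(cloud.points) + [7.0, -3.0, 2.0],
                           cloud.normals @ T.rotation.T)
        _, v1 = volume_pb(moved, PoissonParams(grid_resolution=96))
        assert abs(v1 - v0) / v0 < 0.01


class TestMeasureAll:
    def test_sphere_ordering(self):
        # every Delaunay circumsphere of exact sphere samples is the sphere
        # itself, so alpha must exceed its radius to keep any tetrahedra
        report = measure_all(sphere_cloud(6000),
                             MeasureConfig(alpha=6.0, poisson=PoissonParams(96)))
        assert report.v_gm > report.v_ch >= report.v_as - 1e-6
        assert report.v_pb == pytest.approx(report.v_ch, rel=0.06)
        assert report.v_pb == pytest.approx(SPHERE_VOL, rel=0.05)

    def test_estimator_failure_recorded_not_fatal(self, rng):
        cloud = PointCloud(rng.uniform(0, 100, (60, 3)))
        report = measure_all(cloud, MeasureConfig(alpha=0.001, methods=("gm", "as")))
        assert report.v_as is None
        assert any(w.startswith("as:") for w in report.warnings)
        assert report.v_gm is not None

    def test_report_dict_shape(self):
        report = measure_all(sphere_cloud(3000),
                             MeasureConfig(methods=("gm", "ch"), alpha=3.0))
        d = report.to_dict()
        assert set(d) >= {"sample_id", "size", "v_gm", "v_ch"}
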