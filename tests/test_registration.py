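import numpy as np
import pytest
from scipy.spatial import cKDTree

from bunchmetric.errors import ArgumentError, DegenerateGeometryError, RegistrationError
from bunchmetric.geometry import PointCloud, RigidTransform
from bunchmetric.registration import (
    ICPParams,
    MLSParams,
    coarse_align,
    downsample,
    icp,
    merge_views,
    mls_smooth,
    pca_frame,
)
from bunchmetric.synth import BunchSpec, ScanSpec, generate_bunch, scan_views

from conftest import sphere_cloud


class TestPCAFrame:
    def test_dominant_axis(self, rng):
        pts = np.column_stack([
            rng.uniform(-10, 10, 2000),
            0.01 * rng.normal(size=2000),
            0.01 * rng.normal(size=2000),
        ])
        frame = pca_frame(PointCloud(pts))
        assert abs(frame.axes[0, 0]) > np.cos(np.deg2rad(1))
        assert frame.eigenvalues[0] >= frame.eigenvalues[1] >= frame.eigenvalues[2]
        assert np.linalg.det(frame.axes) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_equivariance(self, rng):
        pts = rng.normal(size=(500, 3)) * np.array([5.0, 2.0, 1.0])
        T = RigidTransform.about_y(41.0)
        f0 = pca_frame(PointCloud(pts))
        f1 = pca_frame(PointCloud(T.apply(pts)))
        # rotated frame must equal the rotation of the original frame, up to
        # the per-axis sign convention
        for j in range(3):
            c = abs(np.dot(f1.axes[:, j], T.rotation @ f0.axes[:, j]))
            assert c > np.cos(np.deg2rad(0.5))

    def test_isotropic_blob_no_crash(self, rng):
        f = pca_frame(PointCloud(rng.normal(size=(10_000, 3))))
        assert f.eigenvalues[0] / f.eigenvalues[2] < 1.1

    def test_collinear_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 50), np.zeros(50), np.zeros(50)])
        with pytest.raises(DegenerateGeometryError):
            pca_frame(PointCloud(pts))


class TestCoarseAlign:
    def test_identity_on_same_cloud(self, rng):
        cloud = PointCloud(rng.normal(size=(800, 3)) * np.array([5, 2, 1]))
        T = coarse_align(cloud, cloud)
        assert T.rotation_angle_deg() < 1e-6
        np.testing.assert_allclose(T.translation, 0, atol=1e-6)

    def test_recovers_rotation_full_overlap(self, rng):
        pts = rng.normal(size=(2000, 3)) * np.array([6.0, 2.5, 1.0])
        pts += 0.2 * rng.normal(size=pts.shape)  # break exact symmetry
        true = RigidTransform.about_y(30.0)
        src = PointCloud(pts)
        tgt = PointCloud(true.apply(pts))
        T = coarse_align(src, tgt)
        err = T.inverse().compose(true)
        assert err.rotation_angle_deg() < 5.0

    def test_matches_exhaustive_candidate_oracle(self, rng):
        pts = rng.normal(size=(600, 3)) * np.array([4.0, 2.0, 1.0])
        src = PointCloud(pts)
        tgt = PointCloud(RigidTransform.about_y(25.0).apply(pts))
        chosen = coarse_align(src, tgt)
        fs, ft = pca_frame(src), pca_frame(tgt)
        tree = cKDTree(tgt.points[
            (np.arange(min(2000, len(tgt))) * len(tgt) // min(2000, len(tgt)))])
        sub = src.points[(np.arange(500) * len(src) // 500)]
        costs = []
        for signs in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
            R = ft.axes @ np.diag(signs) @ fs.axes.T
            cand = RigidTransform(R, ft.centroid - R @ fs.centroid)
            costs.append(tree.query(cand.apply(sub))[0].sum())
        best_cost = min(costs)
        chosen_cost = tree.query(chosen.apply(sub))[0].sum()
        assert chosen_cost == pytest.approx(best_cost, rel=1e-9)


class TestICP:
    def test_identical_clouds_converge_immediately(self, rng):
        cloud = PointCloud(rng.normal(size=(500, 3)))
        res = icp(cloud, cloud, RigidTransform.identity(), ICPParams())
        assert res.iterations == 1
        assert res.rmse < 1e-9

    def test_rmse_non_increasing_on_full_overlap(self, rng):
        pts = rng.normal(size=(1500, 3)) * np.array([5, 3, 1])
        true = RigidTransform.about_y(10.0)
        src, tgt = PointCloud(pts), PointCloud(true.apply(pts))
        res = icp(src, tgt, RigidTransform.identity(),
                  ICPParams(max_correspondence_distance=10.0))
        diffs = np.diff(res.rmse_history)
        assert np.all(diffs <= 1e-9)
        err = res.transform.inverse().compose(true)
        assert err.rotation_angle_deg() < 0.1

    def test_noiseless_adjacent_views_recover_pose(self):
        bunch = generate_bunch(BunchSpec(seed=3))
        views = scan_views(bunch, ScanSpec(noise_sd=0.0, points_per_view=3000), seed=3)
        true_rel = views[0].pose.inverse().compose(views[1].pose)
        init = coarse_align(views[1].cloud, views[0].cloud)
        res = icp(views[1].cloud, views[0].cloud, init,
                  ICPParams(point_to_plane=True, mutual=True))
        err = res.transform.inverse().compose(true_rel)
        assert err.rotation_angle_deg() < 1.0
        assert np.linalg.norm(err.translation) < 0.1

    def test_gross_init_worse_than_coarse(self):
        # mirrors the qualitative comparison of starting ICP raw vs after
        # the PCA coarse alignment on an asymmetric object
        bunch = generate_bunch(BunchSpec(seed=3))
        views = scan_views(bunch, ScanSpec(noise_sd=0.0, points_per_view=2000), seed=3)
        src, tgt = views[1].cloud, views[0].cloud
        flipped = RigidTransform.about_y(180.0)
        params = ICPParams()
        res_flip = icp(src, tgt, flipped, params)
        res_coarse = icp(src, tgt, coarse_align(src, tgt), params)
        assert res_coarse.rmse < res_flip.rmse

    def test_no_overlap_error(self, rng):
        a = PointCloud(rng.normal(size=(100, 3)))
        b = PointCloud(rng.normal(size=(100, 3)) + 100.0)
        with pytest.raises(RegistrationError):
            icp(a, b, RigidTransform.identity(), ICPParams())


class TestMergeViews:
    def test_wrong_view_count(self, rng):
        views = [PointCloud(rng.normal(size=(50, 3))) for _ in range(11)]
        with pytest.raises(ArgumentError):
            merge_views(views)

    def test_noiseless_merge_lies_on_surface(self):
        bunch = generate_bunch(BunchSpec(seed=3))
        views = scan_views(bunch, ScanSpec(noise_sd=0.0, points_per_view=2000), seed=3)
        res = merge_views([v.cloud for v in views])
        pts = views[1].pose.apply(res.cloud.points)  # final frame = view-1 frame
        d = np.linalg.norm(pts[:, None] - bunch.centers[None], axis=2) - bunch.radii[None]
        assert np.abs(d).min(axis=1).max() < 0.1

    def test_pretransformed_views_near_noop(self):
        bunch = generate_bunch(BunchSpec(berry_count=40, seed=4))
        scan = ScanSpec(noise_sd=0.2, points_per_view=3000)
        views = scan_views(bunch, scan, seed=4)
        aligned = [PointCloud(v.pose.apply(v.cloud.points)) for v in views]
        res = merge_views(aligned)
        for entry in res.log:
            if entry["stage"] in ("triple", "quarter"):
                assert entry["rmse"] < 2 * scan.noise_sd
        # inputs already share a frame, so all recovered poses must agree up
        # to a common gauge: relative poses stay near identity
        for i in range(len(res.poses) - 1):
            rel = res.poses[i].inverse().compose(res.poses[i + 1])
            assert rel.rotation_angle_deg() < 2.0
            # half the standard view density here, so allow a looser bound
            assert np.linalg.norm(rel.translation) < 0.3

    def test_logs_every_pairwise_step(self):
        bunch = generate_bunch(BunchSpec(berry_count=30, seed=5))
        views = scan_views(bunch, ScanSpec(points_per_view=1200), seed=5)
        res = merge_views([v.cloud for v in views], refine_passes=0)
        stages = [e["stage"] for e in res.log]
        assert stages.count("triple") == 8
        assert stages.count("quarter") == 3


class TestDownsample:
    def test_collapses_duplicates(self):
        cloud = PointCloud(np.tile([[1.0, 2.0, 3.0]], (1000, 1)))
        out = downsample(cloud, 0.5)
        assert len(out) == 1
        np.testing.assert_allclose(out.points[0], [1, 2, 3], atol=1e-12)

    def test_grid_aligned_lattice_preserved(self):
        ax = np.arange(8) + 0.5
        pts = np.array(np.meshgrid(ax, ax, ax)).reshape(3, -1).T
        out = downsample(PointCloud(pts), 1.0)
        assert len(out) == len(pts)

    def test_count_equals_voxel_occupancy(self, rng):
        from bunchmetric.geometry import voxelize

        cloud = PointCloud(rng.uniform(0, 10, (3000, 3)))
        edge = 0.7
        assert len(downsample(cloud, edge)) == voxelize(cloud, edge).count

    def test_normals_renormalized(self):
        cloud = sphere_cloud(3000)
        out = downsample(cloud, 0.8)
        np.testing.assert_allclose(np.linalg.norm(out.normals, axis=1), 1.0, atol=1e-9)


class TestMLS:
    def test_plane_is_fixed_point(self, rng):
        pts = np.column_stack([rng.uniform(0, 10, 1500), rng.uniform(0, 10, 1500),
                               np.zeros(1500)])
        out = mls_smooth(PointCloud(pts), MLSParams(radius=1.2, h=0.6))
        np.testing.assert_allclose(out.points, pts, atol=1e-9)

    def test_noise_reduced_on_plane(self, rng):
        base = np.column_stack([rng.uniform(0, 10, 3000), rng.uniform(0, 10, 3000),
                                np.zeros(3000)])
        noisy = base + np.column_stack([np.zeros((3000, 2)), rng.normal(0, 0.2, 3000)[:, None]])
        out = mls_smooth(PointCloud(noisy), MLSParams(radius=1.2, h=0.6))
        assert out.points[:, 2].std() < 0.5 * noisy[:, 2].std()

    def test_ghost_sheets_collapse(self, rng):
        n = 3000
        pts = np.column_stack([
            rng.uniform(-5, 5, n), rng.uniform(-5, 5, n),
            np.where(rng.random(n) < 0.5, 0.15, -0.15),
        ])
        out = mls_smooth(PointCloud(pts), MLSParams(radius=1.2, h=0.6))
        assert out.points[:, 2].std() < pts[:, 2].std() / 4
        assert abs(out.points[:, 2].mean()) < 0.05

    def test_never_moves_beyond_radius(self, rng):
        pts = rng.normal(size=(800, 3)) * 2
        params = MLSParams(radius=1.0, h=0.5)
        out = mls_smooth(PointCloud(pts), params)
        moved = np.linalg.norm(out.points - pts, axis=1)
        assert moved.max() <= params.radius + 1e-9

    def test_sparse_points_flagged(self, rng):
        pts = np.vstack([rng.normal(size=(200, 3)), [[100.0, 100.0, 100.0]]])
        out, mask = mls_smooth(PointCloud(pts), MLSParams(radius=1.0, h=0.5),
                               return_mask=True)
        assert mask[-1]
        np.testing.assert_array_equal(out.points[-1], pts[-1])

    def test_param_validation(self):
        with pytest.raises(ArgumentError):
            MLSParams(radius=0.5, h=1.0)
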