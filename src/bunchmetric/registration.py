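"""Multi-view registration into the complete bunch model P0.

The pipeline: PCA coarse alignment (centroid + principal axes, resolving the
four right-handed sign ambiguities by a nearest-neighbor cost on a small
subsample), point-to-point ICP with a hard correspondence cutoff and the
SVD closed-form rigid update, a hierarchical merge (views in triples around
their middle view, then the quarter-models merged sequentially), voxel-grid
downsampling, and moving-least-squares smoothing to collapse the doubled
"ghost" surfaces that imperfect pairwise registration leaves behind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ArgumentError, DegenerateGeometryError, RegistrationError
from .geometry import PointCloud, RigidTransform, pca_eigenframe, voxel_indices

__all__ = [
    "PCAFrame", "ICPParams", "MLSParams", "ICPResult", "MergeResult",
    "pca_frame", "coarse_align", "icp", "merge_views", "downsample", "mls_smooth",
]


@dataclass
class PCAFrame:
    """Centroid + orthonormal axes (columns, by descending eigenvalue)."""

    centroid: np.ndarray
    axes: np.ndarray
    eigenvalues: np.ndarray


@dataclass(frozen=True)
class ICPParams:
    max_iterations: int = 60
    translation_tolerance: float = 1e-4   # cm per iteration
    rotation_tolerance: float = 1e-3      # degrees per iteration
    max_correspondence_distance: float = 1.5  # cm
    downsample_edge: float = 0.0          # cm; 0 disables pre-downsampling
    mutual: bool = False                  # keep only reciprocal nearest pairs
    trim_fraction: float | None = None    # keep this quantile of closest pairs
    point_to_plane: bool = False          # minimize distance to local tangent planes
    normal_max_angle: float | None = None  # degrees; reject matches whose normals disagree

    def __post_init__(self) -> None:
        if (self.max_iterations < 1 or self.translation_tolerance <= 0
                or self.rotation_tolerance <= 0 or self.max_correspondence_distance <= 0
                or self.downsample_edge < 0):
            raise ArgumentError("invalid ICP parameters")
        if self.trim_fraction is not None and not 0.2 <= self.trim_fraction <= 1.0:
            raise ArgumentError("trim_fraction must lie in [0.2, 1]")


@dataclass(frozen=True)
class MLSParams:
    radius: float = 1.2       # cm, neighborhood for the local plane fit
    h: float = 0.6            # cm, Gaussian bandwidth of the weights
    polynomial_order: int = 1

    def __post_init__(self) -> None:
        if not self.radius >= self.h > 0:
            raise ArgumentError("need radius >= h > 0")
        if self.polynomial_order != 1:
            raise ArgumentError("only plane (order-1) MLS is implemented")


@dataclass
class ICPResult:
    transform: RigidTransform
    rmse: float
    iterations: int
    rmse_history: list = field(default_factory=list)


@dataclass
class MergeResult:
    """Merged model plus per-view poses into the final frame and a step log."""

    cloud: PointCloud
    poses: list
    log: list


def pca_frame(cloud: PointCloud) -> PCAFrame:
    """Intrinsic frame of a cloud from the eigen-decomposition of its covariance."""
    centroid, axes, eigenvalues = pca_eigenframe(cloud.points)
    return PCAFrame(centroid, axes, eigenvalues)


def _subsample(points: np.ndarray, n: int) -> np.ndarray:
    if len(points) <= n:
        return points
    step = len(points) / n
    idx = (np.arange(n) * step).astype(int)
    return points[idx]


def coarse_align(source: PointCloud, target: PointCloud) -> RigidTransform:
    """Rough alignment mapping the source PCA frame onto the target's.

    PCA axes are sign-ambiguous; of the four right-handed sign combinations
    the candidate with the smallest summed nearest-neighbor distance on a
    500-point subsample wins.
    """
    fs, ft = pca_frame(source), pca_frame(target)
    tree = cKDTree(_subsample(target.points, 2000))
    sub = _subsample(source.points, 500)
    best, best_cost = None, np.inf
    for signs in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        S = np.diag(signs)
        R = ft.axes @ S @ fs.axes.T
        t = ft.centroid - R @ fs.centroid
        cand = RigidTransform(R, t)
        cost = tree.query(cand.apply(sub))[0].sum()
        if cost < best_cost:
            best, best_cost = cand, cost
    return best


def _best_rigid(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid motion src -> dst (Kabsch/SVD)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cd - R @ cs)


def _best_rigid_p2l(src: np.ndarray, dst: np.ndarray, dst_normals: np.ndarray) -> RigidTransform:
    """Linearized point-to-plane rigid update src -> dst.

    Minimizes sum_i (n_i . (R p_i + t - q_i))^2 in the small-angle
    approximation; adequate inside an ICP loop where per-iteration motion is
    small.
    """
    b = -np.einsum("ij,ij->i", dst_normals, src - dst)
    A = np.hstack([np.cross(src, dst_normals), dst_normals])
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    w, t = x[:3], x[3:]
    theta = np.linalg.norm(w)
    if theta < 1e-15:
        return RigidTransform(np.eye(3), t)
    k = w / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
    return RigidTransform(R, t)


def icp(source: PointCloud, target: PointCloud,
        init: RigidTransform | None = None,
        params: ICPParams = ICPParams()) -> ICPResult:
    """Point-to-point ICP refining ``init`` so the source maps onto the target.

    Correspondences beyond ``max_correspondence_distance`` are discarded each
    iteration; with ``mutual`` only reciprocal nearest-neighbor pairs are
    kept and with ``trim_fraction`` only that quantile of closest pairs —
    both suppress the bias that points visible in one view but not the
    other exert on a partial-overlap fit.  The update is the SVD closed-form
    rigid motion (reflection guarded).  Stops when the per-iteration
    translation and rotation both drop below tolerance, or at
    ``max_iterations``.
    """
    if len(source) == 0 or len(target) == 0:
        raise ArgumentError("ICP requires non-empty clouds")
    src_pts = source.points
    tgt_pts = target.points
    if params.downsample_edge > 0:
        src_pts = downsample(PointCloud(src_pts), params.downsample_edge).points
        tgt_pts = downsample(PointCloud(tgt_pts), params.downsample_edge).points
    tgt_normals = src_normals = None
    if params.point_to_plane or params.normal_max_angle is not None:
        from .segmentation import estimate_normals_curvature

        if target.normals is not None and len(tgt_pts) == len(target.points):
            tgt_normals = target.normals
        else:
            tgt_normals = estimate_normals_curvature(
                PointCloud(tgt_pts), min(20, len(tgt_pts))).normals
        if source.normals is not None and len(src_pts) == len(source.points):
            src_normals = source.normals
        elif params.normal_max_angle is not None:
            src_normals = estimate_normals_curvature(
                PointCloud(src_pts), min(20, len(src_pts))).normals
    tree = cKDTree(tgt_pts)
    current = init if init is not None else RigidTransform.identity()
    rmse = np.inf
    history: list[float] = []
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        moved = current.apply(src_pts)
        moved_normals = None if src_normals is None else src_normals @ current.rotation.T
        dist, idx = tree.query(moved)
        inlier = dist <= params.max_correspondence_distance
        if params.mutual and np.any(inlier):
            back = cKDTree(moved).query(tgt_pts[idx])[1]
            inlier &= back == np.arange(len(moved))
        if params.normal_max_angle is not None and moved_normals is not None:
            cos_ok = np.einsum("ij,ij->i", moved_normals, tgt_normals[idx])
            inlier &= cos_ok > np.cos(np.deg2rad(params.normal_max_angle))
        if params.trim_fraction is not None and inlier.sum() > 50:
            inlier &= dist <= np.quantile(dist[inlier], params.trim_fraction)
        if not np.any(inlier):
            raise RegistrationError(
                "no correspondences within the cutoff; clouds do not overlap"
            )
        if params.point_to_plane:
            # symmetric variant when both clouds carry normals: residuals
            # along the averaged normal cancel the tangential sliding bias
            # curved surfaces induce in one-sided point-to-plane
            nrm = tgt_normals[idx[inlier]]
            if moved_normals is not None:
                nrm = nrm + moved_normals[inlier]
                norms = np.linalg.norm(nrm, axis=1)
                good = norms > 1e-9
                nrm = nrm[good] / norms[good][:, None]
                update = _best_rigid_p2l(moved[inlier][good], tgt_pts[idx[inlier]][good], nrm)
            else:
                update = _best_rigid_p2l(moved[inlier], tgt_pts[idx[inlier]], nrm)
        else:
            update = _best_rigid(moved[inlier], tgt_pts[idx[inlier]])
        current = update.compose(current)
        rmse = float(np.sqrt(np.mean(
            np.sum((update.apply(moved[inlier]) - tgt_pts[idx[inlier]]) ** 2, axis=1)
        )))
        history.append(rmse)
        if (np.linalg.norm(update.translation) < params.translation_tolerance
                and update.rotation_angle_deg() < params.rotation_tolerance):
            break
    return ICPResult(current, rmse, iterations, history)


def _truncated_cost(source: PointCloud, target_tree: cKDTree,
                    transform: RigidTransform, cutoff: float) -> float:
    """Mean of min(NN distance, cutoff) over the whole source cloud.

    Unlike the inlier RMSE — whose value depends on which pairs each run
    kept — this score is comparable across candidate poses.
    """
    dist, _ = target_tree.query(transform.apply(source.points))
    return float(np.mean(np.minimum(dist, cutoff)))


def _axis_rotation(axis: np.ndarray, angle_deg: float, center: np.ndarray) -> RigidTransform:
    """Rotation about an arbitrary axis through ``center``."""
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
    return RigidTransform(R, center - R @ center)


def _register(source: PointCloud, target: PointCloud, params: ICPParams) -> ICPResult:
    """PCA-frame alignment + ICP, made robust for partial turntable views.

    A visible-hemisphere view carries a systematic PCA bias (the seen half
    always faces the camera), so a single frame-to-frame pose can land far
    outside ICP's basin of attraction, and the 500-point subsample cost that
    picks among the four axis-sign candidates is unreliable on partial
    views.  The registration therefore searches the whole ambiguity class:
    every right-handed sign combination of the frame mapping, swept in yaw
    about the target's dominant (vertical) axis, plus an identity start.
    Candidates are screened by truncated nearest-neighbor cost — a score
    comparable across poses, unlike inlier RMSE — and the best few are
    refined by ICP at the configured then a halved cutoff; the finalist
    with the lowest truncated cost wins.
    """
    from dataclasses import replace

    if params.point_to_plane and target.normals is None:
        from .segmentation import estimate_normals_curvature

        target = estimate_normals_curvature(target, min(20, len(target)))

    candidates = [RigidTransform.identity()]
    try:
        fs, ft = pca_frame(source), pca_frame(target)
        for signs in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
            R = ft.axes @ np.diag(signs) @ fs.axes.T
            base = RigidTransform(R, ft.centroid - R @ fs.centroid)
            for yaw in range(0, 360, 30):
                candidates.append(
                    _axis_rotation(ft.axes[:, 0], float(yaw), ft.centroid).compose(base)
                )
    except (ArgumentError, DegenerateGeometryError):
        pass

    cutoff = params.max_correspondence_distance
    tight_cutoff = 0.53 * cutoff
    tree = cKDTree(target.points)

    # pull each candidate into its local basin with a short ICP, then screen
    # by truncated nearest-neighbor cost — comparable across poses, unlike
    # the inlier RMSE each run reports
    screen_params = replace(params, max_iterations=8)
    screened = []
    for i, cand in enumerate(candidates):
        try:
            res = icp(source, target, cand, screen_params)
        except RegistrationError:
            continue
        cost = _truncated_cost(source, tree, res.transform, tight_cutoff)
        screened.append((cost, i, res.transform))
    if not screened:
        raise RegistrationError("all ICP starts failed (no overlapping structure)")
    screened.sort(key=lambda t: t[:2])

    tight = replace(params, max_correspondence_distance=tight_cutoff)
    finalists = []
    for _, _, pose in screened[:3]:
        try:
            stage1 = icp(source, target, pose, params)
            stage2 = icp(source, target, stage1.transform, tight)
        except RegistrationError:
            continue
        cost = _truncated_cost(source, tree, stage2.transform, tight_cutoff)
        finalists.append((cost, stage2))
    if not finalists:
        raise RegistrationError("refinement failed for every candidate start")
    return min(finalists, key=lambda t: t[0])[1]


#: Matching defaults for view merging.  Point-to-plane minimization lets
#: correct structure slide tangentially into place instead of locking into
#: the berry-scale false minima that plain point-to-point matching exhibits
#: on noisy sphere-packed surfaces; reciprocal correspondences suppress the
#: pull of points visible in only one view.
MERGE_ICP_PARAMS = ICPParams(point_to_plane=True, mutual=True,
                             normal_max_angle=25.0, trim_fraction=0.85)


def merge_views(views: list[PointCloud], params: ICPParams = MERGE_ICP_PARAMS,
                refine_passes: int = 2) -> MergeResult:
    """Hierarchically merge an ordered ring of views into one model.

    Twelve views are grouped into triples; within each triple the outer
    views are registered to the middle one and concatenated into a quarter
    model; the quarters are then registered sequentially (each to the model
    merged so far) into the final cloud.  Any view count divisible by 3 (or,
    failing that, 4) is accepted.  Per-pair RMSEs and iteration counts are
    logged, and the absolute pose of every input view in the final frame is
    returned.
    """
    n = len(views)
    if n % 3 == 0:
        group_size = 3
    elif n % 4 == 0:
        group_size = 4
    else:
        raise ArgumentError(
            f"view count {n} is not divisible into groups of 3 or 4 "
            "(the acquisition protocol uses 12)"
        )
    log: list[dict] = []
    if params.point_to_plane:
        # estimate per-view normals once; they rotate along with the poses,
        # so every later registration target arrives with normals attached
        from .segmentation import estimate_normals_curvature

        views = [
            v if v.normals is not None else estimate_normals_curvature(v, min(20, len(v)))
            for v in views
        ]
    group_clouds: list[PointCloud] = []
    group_poses: list[list[RigidTransform]] = []  # pose of each member in its group frame
    for g in range(n // group_size):
        members = list(range(g * group_size, (g + 1) * group_size))
        ref = members[len(members) // 2]
        poses: dict[int, RigidTransform] = {ref: RigidTransform.identity()}
        parts = [views[ref]]
        for m in members:
            if m == ref:
                continue
            try:
                res = _register(views[m], views[ref], params)
            except RegistrationError as exc:
                raise RegistrationError(f"registering view {m} to view {ref}: {exc}") from exc
            poses[m] = res.transform
            parts.append(views[m].transformed(res.transform))
            log.append({"stage": "triple", "source": m, "target": ref,
                        "rmse": res.rmse, "iterations": res.iterations})
        group_clouds.append(PointCloud.concatenate(parts))
        group_poses.append([poses[m] for m in members])

    from dataclasses import replace

    model = group_clouds[0]
    group_to_final = [RigidTransform.identity()]
    tight = replace(params, max_correspondence_distance=0.53 * params.max_correspondence_distance)
    for g in range(1, len(group_clouds)):
        # initialize from the boundary pair: the first view of this group is
        # adjacent to the last view of the previous one, and adjacent-view
        # registration is unambiguous where whole-quarter matching is not
        first, last_prev = g * group_size, g * group_size - 1
        try:
            adj = _register(views[first], views[last_prev], params)
            pose_last_prev = group_to_final[g - 1].compose(
                group_poses[g - 1][group_size - 1])
            init = pose_last_prev.compose(adj.transform).compose(
                group_poses[g][0].inverse())
            res = icp(group_clouds[g], model, init, params)
            res = icp(group_clouds[g], model, res.transform, tight)
            res = icp(group_clouds[g], model, res.transform,
                      replace(params, max_correspondence_distance=0.3 * params.max_correspondence_distance))
        except RegistrationError as exc:
            raise RegistrationError(f"registering quarter {g} to the merged model: {exc}") from exc
        group_to_final.append(res.transform)
        model = PointCloud.concatenate(
            [model, group_clouds[g].transformed(res.transform)]
        )
        log.append({"stage": "quarter", "source": g, "target": "model",
                    "rmse": res.rmse, "iterations": res.iterations})

    poses_final = []
    for g in range(n // group_size):
        for local in group_poses[g]:
            poses_final.append(group_to_final[g].compose(local))

    # polish: re-register every view against the union of all the others.
    # Each view then sees dense structure on both sides, which removes most
    # of the residual bias a single partial-overlap pair leaves behind.
    for _ in range(refine_passes):
        transformed = [views[i].transformed(poses_final[i]) for i in range(n)]
        for i in range(n):
            rest = PointCloud.concatenate([transformed[j] for j in range(n) if j != i])
            try:
                res = icp(views[i], rest, poses_final[i], params)
                res = icp(views[i], rest, res.transform, tight)
            except RegistrationError:
                continue  # keep the hierarchical pose for this view
            poses_final[i] = res.transform
            transformed[i] = views[i].transformed(res.transform)
            log.append({"stage": "polish", "source": i, "target": "rest",
                        "rmse": res.rmse, "iterations": res.iterations})
    model = PointCloud.concatenate([views[i].transformed(poses_final[i]) for i in range(n)])
    return MergeResult(model, poses_final, log)


def downsample(cloud: PointCloud, edge: float) -> PointCloud:
    """Voxel-grid downsampling: one centroid per occupied cell.

    Normals are averaged and renormalized when present; curvatures averaged.
    """
    if edge <= 0:
        raise ArgumentError("edge must be positive")
    idx = voxel_indices(cloud, edge)
    _, inverse, counts = np.unique(idx, axis=0, return_inverse=True, return_counts=True)
    m = counts.shape[0]
    pts = np.zeros((m, 3))
    np.add.at(pts, inverse, cloud.points)
    pts /= counts[:, None]
    normals = None
    if cloud.normals is not None:
        normals = np.zeros((m, 3))
        np.add.at(normals, inverse, cloud.normals)
        norms = np.linalg.norm(normals, axis=1)
        # a cell whose normals cancel falls back to +Z
        normals[norms < 1e-12] = (0.0, 0.0, 1.0)
        norms = np.maximum(norms, 1e-12)
        normals /= np.linalg.norm(normals, axis=1)[:, None]
    curv = None
    if cloud.curvatures is not None:
        curv = np.zeros(m)
        np.add.at(curv, inverse, cloud.curvatures)
        curv /= counts
    return PointCloud(pts, normals, curv)


def mls_smooth(cloud: PointCloud, params: MLSParams = MLSParams(),
               return_mask: bool = False):
    """Moving-least-squares smoothing by projection onto local weighted planes.

    For each point the plane minimizing ``sum_i <n, p_i - q>^2 * theta(|p_i - q|)``
    with Gaussian weights ``theta(d) = exp(-d^2 / h^2)`` is fitted over the
    neighbors within ``radius`` and the point is projected onto it; the fit
    is iterated twice with the weights recentred on the projection.  Points
    with fewer than 4 neighbors pass through unchanged (flagged in the
    optional mask).  No point moves farther than ``radius``.
    """
    pts = cloud.points
    n = len(pts)
    if n < 10:
        raise ArgumentError("MLS needs at least 10 points")
    tree = cKDTree(pts)
    neighbor_lists = tree.query_ball_point(pts, params.radius)
    out = pts.copy()
    normals_out = np.tile([0.0, 0.0, 1.0], (n, 1))
    passthrough = np.zeros(n, dtype=bool)
    h2 = params.h * params.h
    for i in range(n):
        nbr = pts[neighbor_lists[i]]
        if len(nbr) < 4:
            passthrough[i] = True
            if cloud.normals is not None:
                normals_out[i] = cloud.normals[i]
            continue
        q = pts[i]
        normal = None
        for _ in range(2):
            d2 = np.sum((nbr - q) ** 2, axis=1)
            w = np.exp(-d2 / h2)
            wsum = w.sum()
            mu = (w[:, None] * nbr).sum(axis=0) / wsum
            X = nbr - mu
            C = (w[:, None] * X).T @ X / wsum
            evals, evecs = np.linalg.eigh(C)
            normal = evecs[:, 0]
            q = pts[i] - np.dot(pts[i] - mu, normal) * normal
        move = q - pts[i]
        dist = np.linalg.norm(move)
        if dist > params.radius:  # clamp pathological fits
            q = pts[i] + move * (params.radius / dist)
        out[i] = q
        ref = cloud.normals[i] if cloud.normals is not None else np.array([0.0, 0.0, 1.0])
        if np.dot(normal, ref) < 0:
            normal = -normal
        normals_out[i] = normal
    result = PointCloud(out, normals_out / np.linalg.norm(normals_out, axis=1)[:, None])
    return (result, passthrough) if return_mask else result
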