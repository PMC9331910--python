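"""Single-view bunch extraction: crop filter + curvature-seeded region growing.

The raw view contains the bunch, the positioning plate behind it and stray
outliers.  Cropping by coordinate ranges removes the bulk of the scene, then
region growing — seeded at the point of minimum curvature, admitting a
neighbor when its normal is within an angle threshold of the current seed's
normal, and promoting it to a seed when its own curvature is low enough —
splits the remainder into smooth connected clusters.  The bunch is taken to
be the largest surviving cluster.

Curvature here is the *surface variation* lambda_min / (l0 + l1 + l2) of the
local covariance eigenvalues, the usual convention for region growing; it is
0 on a plane and at most 1/3 for an isotropic neighborhood.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ArgumentError, BunchmetricError, SegmentationError
from .geometry import PointCloud

__all__ = [
    "CropBox", "RegionGrowingParams",
    "crop", "estimate_normals_curvature", "region_grow", "segment_bunch",
]


@dataclass(frozen=True)
class CropBox:
    """Closed per-axis keep-ranges in cm; an absent range keeps everything."""

    x_range: tuple[float, float] | None = None
    y_range: tuple[float, float] | None = None
    z_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for r in (self.x_range, self.y_range, self.z_range):
            if r is not None and not r[0] < r[1]:
                raise ArgumentError(f"crop range must satisfy min < max, got {r}")


@dataclass(frozen=True)
class RegionGrowingParams:
    neighbor_count: int = 30        # k for normals/curvature and adjacency
    angle_threshold: float = 60.0   # degrees, vs the current seed's normal
    curvature_threshold: float = 0.3  # promotion-to-seed bound
    min_cluster_size: int = 400

    def __post_init__(self) -> None:
        if not 0 < self.angle_threshold < 90:
            raise ArgumentError("angle_threshold must lie in (0, 90) degrees")
        if not 0 < self.curvature_threshold < 1:
            raise ArgumentError("curvature_threshold must lie in (0, 1)")
        if self.neighbor_count < 4:
            raise ArgumentError("neighbor_count must be >= 4")


def crop(cloud: PointCloud, box: CropBox) -> PointCloud:
    """Keep points whose coordinates satisfy every present closed range."""
    keep = np.ones(len(cloud), dtype=bool)
    for axis, rng in enumerate((box.x_range, box.y_range, box.z_range)):
        if rng is not None:
            keep &= (cloud.points[:, axis] >= rng[0]) & (cloud.points[:, axis] <= rng[1])
    return cloud.select(keep)


def estimate_normals_curvature(cloud: PointCloud, k: int = 30) -> PointCloud:
    """Per-point normal and surface variation from the k-nearest neighborhood.

    The normal is the eigenvector of the smallest covariance eigenvalue,
    flipped to face the +Z camera half-space; curvature is
    lambda_min / (sum of eigenvalues), in [0, 1/3].  Degenerate
    neighborhoods (duplicated points, zero spread) yield curvature 0 and a
    +Z normal rather than NaNs.
    """
    n = len(cloud)
    if k > n:
        raise ArgumentError(f"k={k} exceeds cloud size {n}")
    tree = cKDTree(cloud.points)
    _, idx = tree.query(cloud.points, k=k)
    if k == 1:
        idx = idx[:, None]
    nbrs = cloud.points[idx]                       # (n, k, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / k
    evals, evecs = np.linalg.eigh(cov)             # ascending eigenvalues
    total = evals.sum(axis=1)
    curvature = np.where(total > 1e-300, evals[:, 0] / np.where(total > 0, total, 1.0), 0.0)
    normals = evecs[:, :, 0]
    # orient toward the camera on +Z; break exact ties toward +Z too
    flip = normals[:, 2] < 0
    normals[flip] = -normals[flip]
    degenerate = total <= 1e-300
    normals[degenerate] = (0.0, 0.0, 1.0)
    norms = np.linalg.norm(normals, axis=1)
    normals = normals / np.where(norms > 0, norms, 1.0)[:, None]
    return PointCloud(cloud.points.copy(), normals, np.clip(curvature, 0.0, 1.0))


def region_grow(cloud: PointCloud, params: RegionGrowingParams) -> list[np.ndarray]:
    """Cluster a cloud with normals+curvatures; returns index arrays, largest first.

    Deterministic: regions are seeded in order of (curvature, index); a
    neighbor joins when the angle between its normal and the expanding
    seed's normal is below the threshold, and becomes a seed itself when its
    curvature is below the curvature threshold.  Clusters smaller than
    ``min_cluster_size`` are dropped.
    """
    if cloud.normals is None or cloud.curvatures is None:
        raise BunchmetricError("region_grow needs normals and curvatures; "
                               "run estimate_normals_curvature first")
    n = len(cloud)
    k = min(params.neighbor_count, n)
    tree = cKDTree(cloud.points)
    _, neighbor_idx = tree.query(cloud.points, k=k)
    if k == 1:
        neighbor_idx = neighbor_idx[:, None]
    normals = cloud.normals
    cos_thresh = np.cos(np.deg2rad(params.angle_threshold))
    assigned = np.full(n, -1, dtype=int)
    seed_order = np.lexsort((np.arange(n), cloud.curvatures))
    clusters: list[np.ndarray] = []
    label = 0
    cursor = 0
    while True:
        while cursor < n and assigned[seed_order[cursor]] >= 0:
            cursor += 1
        if cursor >= n:
            break
        root = seed_order[cursor]
        assigned[root] = label
        members = [root]
        queue = deque([root])
        while queue:
            s = queue.popleft()
            ns = normals[s]
            for nb in neighbor_idx[s]:
                if assigned[nb] >= 0:
                    continue
                # unoriented angle: the +Z orientation pass leaves arbitrary
                # signs for normals perpendicular to the camera axis
                if abs(float(np.dot(normals[nb], ns))) > cos_thresh:
                    assigned[nb] = label
                    members.append(nb)
                    if cloud.curvatures[nb] < params.curvature_threshold:
                        queue.append(nb)
        clusters.append(np.array(sorted(members), dtype=int))
        label += 1
    clusters = [c for c in clusters if len(c) >= params.min_cluster_size]
    clusters.sort(key=lambda c: (-len(c), c[0] if len(c) else 0))
    return clusters


def segment_bunch(cloud: PointCloud, box: CropBox | None = None,
                  params: RegionGrowingParams | None = None) -> PointCloud:
    """Crop, estimate normals/curvature, region-grow, return the largest cluster."""
    params = params or RegionGrowingParams()
    cropped = crop(cloud, box) if box is not None else cloud
    if len(cropped) < params.neighbor_count:
        raise SegmentationError(
            f"only {len(cropped)} points remain after cropping; cannot segment"
        )
    enriched = estimate_normals_curvature(cropped, k=params.neighbor_count)
    clusters = region_grow(enriched, params)
    if not clusters:
        raise SegmentationError("no cluster survived min_cluster_size")
    return enriched.select(clusters[0])


def segment_bunch_indices(cloud: PointCloud, box: CropBox | None = None,
                          params: RegionGrowingParams | None = None) -> np.ndarray:
    """As segment_bunch, but return the winning cluster as indices into
    the *input* cloud (useful when per-point labels must be carried along)."""
    params = params or RegionGrowingParams()
    if box is not None:
        keep = np.ones(len(cloud), dtype=bool)
        for axis, rng in enumerate((box.x_range, box.y_range, box.z_range)):
            if rng is not None:
                keep &= (cloud.points[:, axis] >= rng[0]) & (cloud.points[:, axis] <= rng[1])
        original = np.nonzero(keep)[0]
        cropped = cloud.select(keep)
    else:
        original = np.arange(len(cloud))
        cropped = cloud
    if len(cropped) < params.neighbor_count:
        raise SegmentationError("too few points after cropping")
    enriched = estimate_normals_curvature(cropped, k=params.neighbor_count)
    clusters = region_grow(enriched, params)
    if not clusters:
        raise SegmentationError("no cluster survived min_cluster_size")
    return original[clusters[0]]
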