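"""Shared geometric types and primitives.

All coordinates are centimetres internally.  The types here are deliberately
thin: a point cloud is positions plus optional per-point normals/curvatures,
a mesh is an indexed triangle soup with an explicit watertightness audit, and
a rigid transform is a proper rotation plus translation.  The one non-trivial
numeric primitive is :func:`mesh_volume`, the signed-tetrahedron accumulation
used by the convex-hull, alpha-shape and Poisson volume estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ArgumentError, DegenerateGeometryError, EmptyCloudError, NotWatertightError

__all__ = [
    "PointCloud",
    "TriangleMesh",
    "RigidTransform",
    "VoxelGrid",
    "nearest_neighbors",
    "mesh_volume",
    "voxelize",
]


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ArgumentError(f"expected an (N, 3) array of points, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ArgumentError("point coordinates must be finite")
    return pts


@dataclass
class PointCloud:
    """Positions with optional unit normals and surface-variation curvatures."""

    points: np.ndarray
    normals: np.ndarray | None = None
    curvatures: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if self.normals is not None:
            n = np.asarray(self.normals, dtype=np.float64)
            if n.shape != self.points.shape:
                raise ArgumentError("normals must match points in shape")
            norms = np.linalg.norm(n, axis=1)
            if not np.all(np.abs(norms - 1.0) < 1e-6):
                raise ArgumentError("normals must be unit vectors (|norm - 1| < 1e-6)")
            self.normals = n
        if self.curvatures is not None:
            c = np.asarray(self.curvatures, dtype=np.float64)
            if c.shape != (len(self.points),):
                raise ArgumentError("curvatures must be one scalar per point")
            if np.any(c < -1e-12) or np.any(c > 1.0):
                raise ArgumentError("curvatures must lie in [0, 1]")
            self.curvatures = np.clip(c, 0.0, 1.0)

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, transform: "RigidTransform") -> "PointCloud":
        """Apply a rigid transform; normals rotate, curvatures are invariant."""
        pts = self.points @ transform.rotation.T + transform.translation
        nrm = None if self.normals is None else self.normals @ transform.rotation.T
        return PointCloud(pts, nrm, None if self.curvatures is None else self.curvatures.copy())

    def select(self, index) -> "PointCloud":
        """Subset by integer or boolean index, preserving attached attributes."""
        return PointCloud(
            self.points[index],
            None if self.normals is None else self.normals[index],
            None if self.curvatures is None else self.curvatures[index],
        )

    @staticmethod
    def concatenate(clouds: "list[PointCloud]") -> "PointCloud":
        pts = np.vstack([c.points for c in clouds])
        normals = None
        if all(c.normals is not None for c in clouds):
            normals = np.vstack([c.normals for c in clouds])
        curv = None
        if all(c.curvatures is not None for c in clouds):
            curv = np.concatenate([c.curvatures for c in clouds])
        return PointCloud(pts, normals, curv)


@dataclass
class RigidTransform:
    """Proper rigid motion ``p -> R p + t`` (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if R.shape != (3, 3):
            raise ArgumentError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ArgumentError("rotation must be orthonormal to 1e-9")
        if np.linalg.det(R) < 0:
            raise ArgumentError("rotation must be proper (det +1)")
        self.rotation = R
        self.translation = t

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def about_y(angle_deg: float) -> "RigidTransform":
        """Rotation by ``angle_deg`` about the vertical (Y) axis."""
        a = np.deg2rad(angle_deg)
        c, s = np.cos(a), np.sin(a)
        return RigidTransform(np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]]), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        R = _reorthonormalize(self.rotation @ other.rotation)
        return RigidTransform(R, self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.rad2deg(np.arccos(c)))


def _reorthonormalize(R: np.ndarray) -> np.ndarray:
    # project back onto SO(3) so long composition chains keep the invariant
    U, _, Vt = np.linalg.svd(R)
    Q = U @ Vt
    if np.linalg.det(Q) < 0:
        U[:, -1] *= -1
        Q = U @ Vt
    return Q


@dataclass
class TriangleMesh:
    """Indexed triangle surface; faces wound counter-clockwise seen from outside."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = _as_points(self.vertices)
        f = np.asarray(self.faces, dtype=np.int64)
        if f.ndim != 2 or f.shape[1] != 3:
            raise ArgumentError(f"faces must be (M, 3) vertex-index triples, got {f.shape}")
        if len(f) and (f.min() < 0 or f.max() >= len(self.vertices)):
            raise ArgumentError("face index out of range")
        self.faces = f

    def boundary_edges(self) -> np.ndarray:
        """Directed edges not matched by an opposite partner (empty iff watertight)."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        fwd = {tuple(edge) for edge in e.tolist()}
        unmatched = [edge for edge in e.tolist() if (edge[1], edge[0]) not in fwd]
        return np.array(unmatched, dtype=np.int64).reshape(-1, 2)

    @property
    def is_watertight(self) -> bool:
        return len(self.faces) > 0 and len(self.boundary_edges()) == 0

    def euler_characteristic(self) -> int:
        edges = np.sort(
            np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        n_edges = len(np.unique(edges, axis=0))
        n_verts = len(np.unique(self.faces))
        return n_verts - n_edges + len(self.faces)


@dataclass
class VoxelGrid:
    """Occupancy grid: cubic cells of edge ``edge`` anchored at ``origin``."""

    origin: np.ndarray
    edge: float
    occupied: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ArgumentError("voxel edge must be positive")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)

    @property
    def count(self) -> int:
        return len(self.occupied)

    def volume(self) -> float:
        return self.count * self.edge**3


def nearest_neighbors(query: PointCloud, reference: PointCloud, count: int):
    """``count`` nearest reference points per query point, ascending distance.

    Ties are broken toward the lower reference index so results are fully
    deterministic.  Returns ``(indices, distances)`` arrays of shape
    ``(n_query, count)``.
    """
    if len(reference) == 0:
        raise EmptyCloudError("reference cloud is empty")
    if count < 1 or count > len(reference):
        raise ArgumentError(f"count must be in [1, {len(reference)}], got {count}")
    tree = cKDTree(reference.points)
    dist, idx = tree.query(query.points, k=count)
    if count == 1:
        dist, idx = dist[:, None], idx[:, None]
    # enforce the (distance, index) ordering contract row by row
    order = np.lexsort((idx, dist), axis=1)
    rows = np.arange(len(idx))[:, None]
    return idx[rows, order], dist[rows, order]


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume of a watertight mesh by signed-tetrahedron accumulation.

    Each face (v1, v2, v3) contributes (1/6)(v1 x v2) . v3, the signed volume
    of the tetrahedron it spans with the coordinate origin; for a closed,
    consistently wound surface the signed sum telescopes to the enclosed
    volume regardless of where the origin sits.  The absolute value is
    returned so a globally reversed winding cannot yield a negative volume.
    """
    boundary = mesh.boundary_edges()
    if len(mesh.faces) == 0 or len(boundary):
        first = tuple(boundary[0]) if len(boundary) else None
        raise NotWatertightError(
            f"mesh is not watertight (first boundary edge: {first})"
        )
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    signed = np.einsum("ij,ij->i", np.cross(a, b), c).sum() / 6.0
    return float(abs(signed))


def voxelize(cloud: PointCloud, edge: float, origin: np.ndarray | None = None) -> VoxelGrid:
    """Occupancy grid of the cloud at cell edge ``edge`` (cm).

    The origin defaults to the per-axis minimum of the cloud; pass one
    explicitly for convergence studies where the grid must stay fixed.
    """
    if edge <= 0:
        raise ArgumentError("voxel edge must be positive")
    if len(cloud) == 0:
        raise EmptyCloudError("cannot voxelize an empty cloud")
    if origin is None:
        origin = cloud.points.min(axis=0)
    origin = np.asarray(origin, dtype=np.float64).reshape(3)
    idx = np.floor((cloud.points - origin) / edge).astype(np.int64)
    occupied = set(map(tuple, idx.tolist()))
    return VoxelGrid(origin=origin, edge=float(edge), occupied=occupied)


def voxel_indices(cloud: PointCloud, edge: float, origin: np.ndarray | None = None):
    """Per-point integer cell indices (shared helper for voxelize/downsample)."""
    if edge <= 0:
        raise ArgumentError("voxel edge must be positive")
    if origin is None:
        origin = cloud.points.min(axis=0)
    return np.floor((cloud.points - np.asarray(origin)) / edge).astype(np.int64)


def pca_eigenframe(points: np.ndarray):
    """Centroid, axes (columns, descending variance) and eigenvalues of a cloud.

    Shared by registration (coarse alignment) and measurement (intrinsic
    size frame).  Axis signs follow a fixed convention — each of the first
    two axes is flipped so its largest-magnitude component is positive, the
    third is their cross product — so the frame is unique and right-handed.
    """
    pts = _as_points(points)
    if len(pts) < 4:
        raise DegenerateGeometryError("need at least 4 points for a PCA frame")
    centroid = pts.mean(axis=0)
    X = pts - centroid
    cov = (X.T @ X) / len(pts)
    U, S, _ = np.linalg.svd(cov)
    if S[0] <= 0 or S[1] / S[0] < 1e-12:
        raise DegenerateGeometryError("collinear cloud: covariance is rank deficient")
    axes = U.copy()
    for j in range(2):
        k = np.argmax(np.abs(axes[:, j]))
        if axes[k, j] < 0:
            axes[:, j] = -axes[:, j]
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])
    return centroid, axes, S
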