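"""Size extraction and the five volume estimators.

Sizes are measured in the bunch's own PCA frame: the axis of largest
variance is the bunch's vertical (grape bunches are elongated along the
rachis) and carries the height h; the remaining two axes carry length l and
width w with l >= w by convention.  The estimators:

* GM  — bounding cylinder, pi * (max(l, w)/2)^2 * h.
* CH  — convex hull (quickhull) volume via the signed-tetrahedron sum.
* AS  — alpha-shape: Delaunay tetrahedra with circumsphere radius <= alpha.
* VB  — occupied-voxel count times the unit-cube volume.
* PB  — Poisson reconstruction followed by the mesh volume.

GM, CH and VB bound or envelope the bunch and systematically overestimate a
crevice-riddled object; AS interpolates between the point set and its hull
as alpha grows; PB closes the surface smoothly and tracks the true volume
most closely, erring slightly high because reconstruction bridges the
narrow gaps between berries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .errors import AlphaTooSmallError, ArgumentError, BunchmetricError, DegenerateGeometryError
from .geometry import PointCloud, TriangleMesh, mesh_volume, pca_eigenframe, voxelize
from .poisson import PoissonParams, reconstruct_poisson
from .segmentation import estimate_normals_curvature

logger = logging.getLogger(__name__)

__all__ = [
    "SizeTriple", "AlphaShapeParams", "MeasureConfig", "VolumeReport",
    "size_extent", "volume_gm", "volume_convex_hull", "volume_alpha_shape",
    "volume_voxel", "volume_pb", "measure_all",
]


@dataclass(frozen=True)
class SizeTriple:
    """Length, width, height of the bunch in cm (l >= w; h along the rachis)."""

    l: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if min(self.l, self.w, self.h) <= 0:
            raise ArgumentError("all sizes must be positive")


@dataclass(frozen=True)
class AlphaShapeParams:
    alpha: float  # cm; circumsphere-radius bound

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ArgumentError("alpha must be positive")


@dataclass(frozen=True)
class MeasureConfig:
    """Estimator configuration for measure_all; lengths in cm."""

    alpha: float = 1.75            # ~1.25x a typical berry radius
    voxel_edge: float = 0.2
    poisson: PoissonParams = field(default_factory=PoissonParams)
    methods: tuple = ("gm", "ch", "as", "vb", "pb")
    size_frame: str = "pca"        # "pca" (intrinsic) or "lab"
    normal_k: int = 30             # for normal re-estimation when absent


@dataclass
class VolumeReport:
    """One measured sample, mirroring a row of the reference table."""

    sample_id: str
    size: SizeTriple | None = None
    v_true: float | None = None
    v_gm: float | None = None
    v_ch: float | None = None
    v_as: float | None = None
    v_vb: float | None = None
    v_pb: float | None = None
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {"sample_id": self.sample_id}
        if self.size is not None:
            d["size"] = {"l": self.size.l, "w": self.size.w, "h": self.size.h}
        for k in ("v_true", "v_gm", "v_ch", "v_as", "v_vb", "v_pb"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        if self.warnings:
            d["warnings"] = list(self.warnings)
        return d


def size_extent(cloud: PointCloud, frame: str = "pca") -> SizeTriple:
    """Axis-aligned extents of the cloud in its intrinsic (PCA) frame.

    ``frame="lab"`` measures along the world axes instead (l=x, w=y, h=z up
    to the l >= w convention).
    """
    if frame == "lab":
        ext = cloud.points.max(axis=0) - cloud.points.min(axis=0)
        h = float(ext[1])  # vertical lab axis
        l, w = sorted((float(ext[0]), float(ext[2])), reverse=True)
    elif frame == "pca":
        centroid, axes, _ = pca_eigenframe(cloud.points)
        local = (cloud.points - centroid) @ axes
        ext = local.max(axis=0) - local.min(axis=0)
        h = float(ext[0])  # largest-eigenvalue axis = rachis direction
        l, w = sorted((float(ext[1]), float(ext[2])), reverse=True)
    else:
        raise ArgumentError("frame must be 'pca' or 'lab'")
    return SizeTriple(l=l, w=w, h=h)


def volume_gm(size: SizeTriple) -> float:
    """Bounding-cylinder volume: the larger of l, w is the diameter."""
    r = max(size.l, size.w) / 2.0
    return float(np.pi * r * r * size.h)


def volume_convex_hull(cloud: PointCloud):
    """Convex hull mesh (outward wound) and its volume.  Returns (mesh, cm^3)."""
    if len(cloud) < 4:
        raise DegenerateGeometryError("convex hull needs at least 4 points")
    try:
        hull = ConvexHull(cloud.points)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate hull input: {exc}") from exc
    faces = hull.simplices.copy()
    # orient each facet so its normal agrees with the qhull outward equation
    v = cloud.points
    normals = np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]])
    flip = np.einsum("ij,ij->i", normals, hull.equations[:, :3]) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    mesh = TriangleMesh(cloud.points.copy(), faces)
    return mesh, mesh_volume(mesh)


def _circumradii(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = points[tets[:, 0]]
    rows = np.stack([points[tets[:, j]] - a for j in (1, 2, 3)], axis=1)  # (m,3,3)
    rhs = 0.5 * np.einsum("mij,mij->mi", rows, rows)
    det = np.linalg.det(rows)
    radii = np.full(len(tets), np.inf)
    ok = np.abs(det) > 1e-12
    if np.any(ok):
        center = np.linalg.solve(rows[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(center, axis=1)
    return radii


def _tet_volumes(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = points[tets[:, 0]]
    m = np.stack([points[tets[:, j]] - a for j in (1, 2, 3)], axis=1)
    return np.abs(np.linalg.det(m)) / 6.0


def volume_alpha_shape(cloud: PointCloud, params: AlphaShapeParams):
    """Alpha-shape mesh and volume: keep Delaunay tetrahedra whose
    circumsphere radius is at most alpha; the volume is the summed volume of
    the kept complex and the mesh is its boundary, outward wound.
    Returns (mesh, cm^3)."""
    if len(cloud) < 4:
        raise DegenerateGeometryError("alpha shape needs at least 4 points")
    try:
        tri = Delaunay(cloud.points)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate Delaunay input: {exc}") from exc
    tets = tri.simplices
    keep = _circumradii(cloud.points, tets) <= params.alpha
    if not np.any(keep):
        raise AlphaTooSmallError(
            f"alpha={params.alpha} keeps no tetrahedra; increase alpha"
        )
    kept = tets[keep]
    volume = float(_tet_volumes(cloud.points, kept).sum())

    # boundary faces: those belonging to exactly one kept tetrahedron
    faces_all = kept[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]].reshape(-1, 3)
    opposite = kept.reshape(-1, 4)[np.repeat(np.arange(len(kept)), 4),
                                   np.tile(np.arange(4), len(kept))]
    key = np.sort(faces_all, axis=1)
    _, first, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    boundary_rows = first[counts == 1]
    bfaces = faces_all[boundary_rows]
    bopp = opposite[boundary_rows]
    p = cloud.points
    n = np.cross(p[bfaces[:, 1]] - p[bfaces[:, 0]], p[bfaces[:, 2]] - p[bfaces[:, 0]])
    inward = np.einsum("ij,ij->i", n, p[bopp] - p[bfaces[:, 0]]) > 0
    bfaces[inward] = bfaces[inward][:, [0, 2, 1]]
    mesh = TriangleMesh(cloud.points.copy(), bfaces)
    return mesh, volume


def volume_voxel(cloud: PointCloud, edge: float) -> float:
    """Occupied-voxel volume: count of occupied cells times edge^3."""
    return voxelize(cloud, edge).volume()


def volume_pb(cloud: PointCloud, params: PoissonParams = PoissonParams()):
    """Poisson reconstruction followed by the mesh volume.  Returns (mesh, cm^3)."""
    mesh = reconstruct_poisson(cloud, params)
    return mesh, mesh_volume(mesh)


def measure_all(cloud: PointCloud, config: MeasureConfig = MeasureConfig(),
                v_true: float | None = None, sample_id: str = "sample") -> VolumeReport:
    """Run size extraction and the configured estimators on a registered cloud.

    Individual estimator failures are recorded as warnings on the report
    rather than raised, so one bad parameter cannot void a whole run.
    """
    report = VolumeReport(sample_id=sample_id, v_true=v_true)
    try:
        report.size = size_extent(cloud, frame=config.size_frame)
    except BunchmetricError as exc:
        report.warnings.append(f"size: {exc}")
        logger.warning("size extraction failed: %s", exc)
    if "gm" in config.methods and report.size is not None:
        report.v_gm = volume_gm(report.size)
    if "ch" in config.methods:
        try:
            _, report.v_ch = volume_convex_hull(cloud)
        except BunchmetricError as exc:
            report.warnings.append(f"ch: {exc}")
            logger.warning("convex hull failed: %s", exc)
    if "as" in config.methods:
        try:
            _, report.v_as = volume_alpha_shape(cloud, AlphaShapeParams(config.alpha))
        except BunchmetricError as exc:
            report.warnings.append(f"as: {exc}")
            logger.warning("alpha shape failed: %s", exc)
    if "vb" in config.methods:
        try:
            report.v_vb = volume_voxel(cloud, config.voxel_edge)
        except BunchmetricError as exc:
            report.warnings.append(f"vb: {exc}")
            logger.warning("voxel volume failed: %s", exc)
    if "pb" in config.methods:
        try:
            oriented = cloud
            if cloud.normals is None:
                oriented = _outward_normals(cloud, config.normal_k)
            _, report.v_pb = volume_pb(oriented, config.poisson)
        except BunchmetricError as exc:
            report.warnings.append(f"pb: {exc}")
            logger.warning("poisson volume failed: %s", exc)
    return report


def _outward_normals(cloud: PointCloud, k: int) -> PointCloud:
    """Estimate normals and orient them away from the centroid.

    Adequate for star-shaped-ish bunches; clouds arriving from the MLS stage
    already carry consistent normals and skip this.
    """
    enriched = estimate_normals_curvature(cloud, k=min(k, len(cloud)))
    normals = enriched.normals.copy()
    outward = cloud.points - cloud.points.mean(axis=0)
    flip = np.einsum("ij,ij->i", normals, outward) < 0
    normals[flip] = -normals[flip]
    return PointCloud(cloud.points.copy(), normals, enriched.curvatures)
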