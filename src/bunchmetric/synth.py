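"""Synthetic grape bunches with known geometry, and a simulated turntable scan.

A bunch is modelled as a connected packing of spherical berries inside a
tapered cylindrical envelope around a vertical (Y) rachis — red table grapes
are large, nearly spherical and space-filling, and the bunch silhouette is
close to a cylinder.  The generator is the package's only source of ground
truth: berry centres and radii are exact, the true volume of the union of
spheres is estimated by Monte-Carlo integration with a binomial standard
error (the in-silico counterpart of weighing displaced water), and the scan
simulator reproduces the acquisition protocol the pipeline targets — 12
views, the bunch rotated 30 degrees about the vertical axis between views, a
depth camera about 1 m away with ~2 mm noise, optionally a positioning plate
behind the bunch plus sparse outliers.

Every stage draws from its own child of a single integer seed, so each
stage's output is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np

from .errors import ArgumentError, GenerationError
from .geometry import PointCloud, RigidTransform

__all__ = [
    "BunchSpec", "Bunch", "ScanSpec", "ScanView",
    "generate_bunch", "true_volume", "sample_surface", "scan_views",
]

_PROFILES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    # envelope radius multiplier vs normalized depth t (0 = top, 1 = bottom)
    "cylinder": lambda t: np.ones_like(t),
    "tapered": lambda t: 1.0 - 0.4 * t,
    "cone": lambda t: 1.0 - 0.8 * t,
}


@dataclass(frozen=True)
class BunchSpec:
    """Parameters of the synthetic bunch; all lengths in cm."""

    berry_count: int = 60
    berry_radius_mean: float = 1.5
    berry_radius_sd: float = 0.12
    bunch_height: float = 14.0
    rachis_profile: str = "tapered"
    packing_overlap: float = 0.25
    cross_section_aspect: float = 1.6  # horizontal l/w of the berry packing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.berry_count < 1:
            raise ArgumentError("berry_count must be >= 1")
        if not self.berry_radius_mean > 3 * self.berry_radius_sd > 0:
            raise ArgumentError("need berry_radius_mean > 3*berry_radius_sd > 0")
        if not 0 <= self.packing_overlap < 0.5:
            raise ArgumentError("packing_overlap must lie in [0, 0.5)")
        if self.rachis_profile not in _PROFILES:
            raise ArgumentError(f"unknown rachis_profile {self.rachis_profile!r}")
        if not 1.0 <= self.cross_section_aspect <= 2.5:
            raise ArgumentError("cross_section_aspect must lie in [1, 2.5]")


@dataclass
class Bunch:
    """Ground-truth geometry: per-berry centres (cm) and radii (cm)."""

    centers: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=np.float64).reshape(-1)
        if len(self.centers) != len(self.radii) or np.any(self.radii <= 0):
            raise ArgumentError("centers/radii mismatch or non-positive radius")

    def __len__(self) -> int:
        return len(self.radii)

    def bounding_box(self):
        lo = (self.centers - self.radii[:, None]).min(axis=0)
        hi = (self.centers + self.radii[:, None]).max(axis=0)
        return lo, hi


@dataclass(frozen=True)
class ScanSpec:
    """Turntable acquisition parameters (defaults mirror the target protocol)."""

    views: int = 12
    step_deg: float = 30.0
    noise_sd: float = 0.2          # cm; ~2 mm depth-camera accuracy
    points_per_view: int = 6000
    background: bool = False       # positioning plate + uniform outliers
    camera_distance: float = 100.0  # cm; ~1 m to the camera on +Z
    outlier_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.views < 1 or self.step_deg <= 0:
            raise ArgumentError("views >= 1 and step_deg > 0 required")
        if abs(self.views * self.step_deg - 360.0) > 1e-9:
            raise ArgumentError("views * step_deg must cover 360 degrees")
        if self.noise_sd < 0:
            raise ArgumentError("noise_sd must be >= 0")


class ScanView(NamedTuple):
    """One simulated view: cloud in view coordinates, pose mapping the view
    back into bunch coordinates, and per-point labels (berry index >= 0,
    -1 = background plate, -2 = outlier)."""

    cloud: PointCloud
    pose: RigidTransform
    labels: np.ndarray


# ---------------------------------------------------------------- bunch


def _lattice_positions(spec: BunchSpec, rng: np.random.Generator,
                       max_rings: int = 5) -> np.ndarray:
    """Candidate berry centres on rings along the rachis, inner rings first.

    Sites are ordered by (ring index, level, angle): the rachis column fills
    before the first ring, the first ring before the second, and so on, so
    a bunch of any berry count spans the full height and widens only as far
    as the count requires — the way berries crowd around a real rachis.
    The tapered envelope profile caps the ring radius available at each
    depth, narrowing the bunch toward its tip.  Ring phases are drawn at
    random per level: real bunches have no rotational symmetry, and an
    artificially periodic berry pattern would hand multi-view registration
    false minima no real scan exhibits.
    """
    profile = _PROFILES[spec.rachis_profile]
    spacing = 2.0 * spec.berry_radius_mean * (1.0 - spec.packing_overlap / 2.0)
    n_levels = max(2, int(np.ceil(spec.bunch_height / (0.85 * spacing))) + 1)
    ys = np.linspace(spec.bunch_height / 2.0, -spec.bunch_height / 2.0, n_levels)
    out = []
    for ring in range(max_rings + 1):
        rho = ring * 0.9 * spacing
        for li, y in enumerate(ys):
            t = (spec.bunch_height / 2.0 - y) / spec.bunch_height
            r_allowed = spec.bunch_height * 0.5 * float(profile(np.array([t]))[0])
            if ring > 0 and rho > r_allowed:
                continue
            if ring == 0:
                out.append((0.0, y, 0.0))
                continue
            n_on_ring = max(1, int(np.floor(2 * np.pi * rho / (0.9 * spacing))))
            phase = rng.uniform(0.0, 1.0)
            for j in range(n_on_ring):
                a = 2 * np.pi * (j + phase) / n_on_ring
                out.append((rho * np.cos(a), y, rho * np.sin(a)))
    return np.array(out)


def _relax(centers, radii, overlap, max_iter=300):
    """Push pairs apart until no pair interpenetrates beyond the allowance."""
    for _ in range(max_iter):
        diff = centers[:, None, :] - centers[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        rsum = radii[:, None] + radii[None, :]
        min_d = rsum * (1.0 - overlap / 2.0)
        np.fill_diagonal(dist, np.inf)
        bad = np.argwhere(dist < min_d)
        if len(bad) == 0:
            return centers, True
        moved = np.zeros_like(centers)
        for i, j in bad[bad[:, 0] < bad[:, 1]]:
            d = dist[i, j]
            target = min_d[i, j] * 1.001
            direction = (centers[i] - centers[j]) / d if d > 1e-9 else np.array([1.0, 0, 0])
            push = 0.5 * (target - d)
            moved[i] += push * direction
            moved[j] -= push * direction
        centers = centers + moved
    return centers, False


def _components(centers, radii, overlap):
    n = len(centers)
    dist = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    rsum = radii[:, None] + radii[None, :]
    adj = dist <= rsum * (1.0 + overlap)
    np.fill_diagonal(adj, False)
    comp = -np.ones(n, dtype=int)
    current = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = current
        while stack:
            k = stack.pop()
            for nb in np.nonzero(adj[k])[0]:
                if comp[nb] < 0:
                    comp[nb] = current
                    stack.append(nb)
        current += 1
    return comp


def generate_bunch(spec: BunchSpec) -> Bunch:
    """Deterministically generate a connected berry packing from a spec."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    n = spec.berry_count

    # radii from the truncated normal (+-3 sd)
    radii = np.empty(n)
    for i in range(n):
        while True:
            r = rng.normal(spec.berry_radius_mean, spec.berry_radius_sd)
            if abs(r - spec.berry_radius_mean) <= 3 * spec.berry_radius_sd:
                radii[i] = r
                break

    if n == 1:
        return Bunch(np.zeros((1, 3)), radii)

    positions = _lattice_positions(spec, rng)
    if len(positions) < n:
        raise GenerationError(
            f"cannot place {n} berries; try fewer berries or a taller bunch"
        )
    # real bunches are not bodies of revolution: stretch the packing along
    # one horizontal axis so the cross-section is elliptical (length > width)
    s = np.sqrt(spec.cross_section_aspect)
    positions = positions * np.array([s, 1.0, 1.0 / s])
    centers = positions[:n] + rng.normal(0.0, 0.22 * spec.berry_radius_mean, (n, 3))

    for _ in range(40):
        centers, ok = _relax(centers, radii, spec.packing_overlap)
        if not ok:
            raise GenerationError("packing relaxation did not converge; reduce berry_count")
        comp = _components(centers, radii, spec.packing_overlap)
        if comp.max() == 0:
            break
        # pull every minor component toward the largest one
        main = np.argmax(np.bincount(comp))
        for c in range(comp.max() + 1):
            if c == main:
                continue
            idx = comp == c
            d = centers[idx][:, None, :] - centers[comp == main][None, :, :]
            dn = np.linalg.norm(d, axis=2)
            i, j = np.unravel_index(np.argmin(dn), dn.shape)
            shift = -d[i, j] / dn[i, j] * (dn[i, j] * 0.25 + 0.1)
            centers[idx] += shift
    else:
        raise GenerationError("could not connect all berries; reduce berry_count")

    centers -= centers.mean(axis=0)
    return Bunch(centers, radii)


# ---------------------------------------------------------------- oracle


def true_volume(bunch: Bunch, samples: int = 10**6, seed: int = 0):
    """Monte-Carlo volume of the union of berry spheres.

    Plays the role of the physical water-displacement measurement: uniform
    samples in the bounding box are tested for membership in any sphere and
    the hit fraction scales the box volume.  Returns ``(volume, standard
    error)`` in cm^3, the SE from the binomial proportion.
    """
    if samples < 10**4:
        raise ArgumentError("use at least 1e4 samples for a meaningful estimate")
    lo, hi = bunch.bounding_box()
    box_vol = float(np.prod(hi - lo))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    hits = 0
    remaining = samples
    r2 = bunch.radii**2
    while remaining > 0:
        m = min(remaining, 200_000)
        pts = rng.uniform(lo, hi, (m, 3))
        inside = np.zeros(m, dtype=bool)
        for c, rr in zip(bunch.centers, r2):
            inside |= np.einsum("ij,ij->i", pts - c, pts - c) <= rr
        hits += int(inside.sum())
        remaining -= m
    p = hits / samples
    volume = box_vol * p
    se = box_vol * np.sqrt(p * (1.0 - p) / samples)
    return float(volume), float(se)


# ---------------------------------------------------------------- sampling


def _sample_surface_labeled(bunch: Bunch, density: float, rng: np.random.Generator):
    if density <= 0:
        raise ArgumentError("density must be positive")
    pts, nrm, ids = [], [], []
    for b, (c, r) in enumerate(zip(bunch.centers, bunch.radii)):
        n = max(4, int(round(density * 4.0 * np.pi * r * r)))
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        p = c + r * v
        # reject samples buried strictly inside another berry
        keep = np.ones(n, dtype=bool)
        for j, (cj, rj) in enumerate(zip(bunch.centers, bunch.radii)):
            if j == b:
                continue
            keep &= np.einsum("ij,ij->i", p - cj, p - cj) >= (rj - 1e-9) ** 2
        pts.append(p[keep])
        nrm.append(v[keep])
        ids.append(np.full(int(keep.sum()), b))
    points = np.vstack(pts)
    normals = np.vstack(nrm)
    return PointCloud(points, normals), np.concatenate(ids)


def sample_surface(bunch: Bunch, density: float = 12.0, seed: int = 0) -> PointCloud:
    """Uniform samples of the union-of-spheres surface with outward normals.

    ``density`` is points per cm^2 of sphere area before crowding rejection;
    samples landing strictly inside a neighbouring berry are discarded, so
    the result covers exactly the exterior surface.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    cloud, _ = _sample_surface_labeled(bunch, density, rng)
    return cloud


# ---------------------------------------------------------------- scanning


def _visible_mask(points, normals, berry_ids, centers, radii, camera):
    """Hidden-point removal by exact sphere/segment intersection."""
    view = camera - points
    facing = np.einsum("ij,ij->i", normals, view) > 0.0
    # does any other berry intersect the segment from the point to the camera?
    d = view  # (M, 3)
    dd = np.einsum("ij,ij->i", d, d)
    occluded = np.zeros(len(points), dtype=bool)
    for j, (c, r) in enumerate(zip(centers, radii)):
        w = c - points
        t = np.clip(np.einsum("ij,ij->i", w, d) / dd, 0.0, 1.0)
        closest = points + t[:, None] * d
        dist2 = np.einsum("ij,ij->i", closest - c, closest - c)
        hit = dist2 < (r - 1e-6) ** 2
        hit &= berry_ids != j  # own sphere handled by the facing test
        occluded |= hit
    return facing & ~occluded


def scan_views(bunch: Bunch, scan: ScanSpec, seed: int = 0) -> list[ScanView]:
    """Simulate the turntable acquisition; returns one labelled view per step.

    For view *i* the bunch is rotated ``i * step_deg`` counterclockwise about
    the vertical Y axis; a camera on +Z at ``camera_distance`` sees only
    front-facing, unoccluded surface points.  Isotropic Gaussian noise of
    ``noise_sd`` is then added, and, when ``background`` is set, a planar
    positioning plate behind the bunch plus uniform outliers are appended.
    Each view's pose maps its coordinates back into bunch coordinates.
    """
    seq = np.random.SeedSequence([seed, 404])
    children = seq.spawn(scan.views)
    area = float(4.0 * np.pi * np.sum(bunch.radii**2))
    density = 2.8 * scan.points_per_view / area
    views = []
    for i in range(scan.views):
        rng = np.random.default_rng(children[i])
        rot = RigidTransform.about_y(i * scan.step_deg)
        centers = rot.apply(bunch.centers)
        rotated = Bunch(centers, bunch.radii.copy())
        cloud, ids = _sample_surface_labeled(rotated, density, rng)
        camera = np.array([0.0, 0.0, scan.camera_distance])
        mask = _visible_mask(cloud.points, cloud.normals, ids, centers, bunch.radii, camera)
        pts, ids_v = cloud.points[mask], ids[mask]
        if len(pts) > scan.points_per_view:
            pick = np.sort(rng.choice(len(pts), scan.points_per_view, replace=False))
            pts, ids_v = pts[pick], ids_v[pick]
        pts = pts + rng.normal(0.0, scan.noise_sd, pts.shape)
        labels = ids_v.astype(int)

        if scan.background:
            lo, hi = rotated.bounding_box()
            z_plate = lo[2] - 6.0
            half_x = 1.6 * max(abs(lo[0]), abs(hi[0])) + 4.0
            n_plate = int(0.4 * scan.points_per_view)
            plate = np.column_stack([
                rng.uniform(-half_x, half_x, n_plate),
                rng.uniform(lo[1] - 3.0, hi[1] + 3.0, n_plate),
                np.full(n_plate, z_plate),
            ])
            plate += rng.normal(0.0, scan.noise_sd, plate.shape)
            n_out = int(np.ceil(scan.outlier_fraction * (len(pts) + n_plate)))
            span_lo = np.minimum(lo, plate.min(axis=0)) - 2.0
            span_hi = np.maximum(hi, plate.max(axis=0)) + 2.0
            outliers = rng.uniform(span_lo, span_hi, (n_out, 3))
            pts = np.vstack([pts, plate, outliers])
            labels = np.concatenate([labels, np.full(n_plate, -1), np.full(n_out, -2)])

        pose = rot.inverse()
        views.append(ScanView(PointCloud(pts), pose, labels))
    return views
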