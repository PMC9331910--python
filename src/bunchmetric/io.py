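"""Point-cloud file I/O: PLY (ASCII and binary little-endian), PCD ASCII, XYZ text.

PLY is the canonical interchange format.  Only the geometry dialect used by
this pipeline is supported — ``x y z`` with optional ``nx ny nz`` as
float32/float64 — which keeps the parser small and the failure messages
specific.  Every written file carries a comment recording the length unit
(centimetres).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import ArgumentError, EmptyCloudError, ParseError
from .geometry import PointCloud

__all__ = ["read_cloud", "write_cloud"]

_PLY_TYPES = {
    "float": ("f", 4), "float32": ("f", 4),
    "double": ("d", 8), "float64": ("d", 8),
    "uchar": ("B", 1), "uint8": ("B", 1), "char": ("b", 1), "int8": ("b", 1),
    "short": ("h", 2), "ushort": ("H", 2), "int16": ("h", 2), "uint16": ("H", 2),
    "int": ("i", 4), "int32": ("i", 4), "uint": ("I", 4), "uint32": ("I", 4),
}


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("ply", "pcd", "xyz", "txt"):
        return "xyz" if suffix == "txt" else suffix
    raise ArgumentError(f"cannot infer format from suffix of {path}; pass format=")


def read_cloud(path, format: str | None = None) -> PointCloud:
    """Read a point cloud, preserving point order; normals loaded if present."""
    path = Path(path)
    fmt = format or _sniff_format(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "pcd":
        return _read_pcd(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ArgumentError(f"unknown format {fmt!r} (expected ply, pcd or xyz)")


def write_cloud(cloud: PointCloud, path, format: str | None = None, binary: bool = False):
    """Write a cloud; normals are emitted iff present.  Returns the path."""
    if len(cloud) == 0:
        raise EmptyCloudError("refusing to write an empty cloud")
    path = Path(path)
    fmt = format or _sniff_format(path)
    if fmt == "ply":
        _write_ply(cloud, path, binary=binary)
    elif fmt == "pcd":
        _write_pcd(cloud, path)
    elif fmt == "xyz":
        _write_xyz(cloud, path)
    else:
        raise ArgumentError(f"unknown format {fmt!r} (expected ply, pcd or xyz)")
    return path


# ---------------------------------------------------------------- PLY

def _read_ply(path: Path) -> PointCloud:
    raw = path.read_bytes()
    if not raw:
        raise EmptyCloudError(f"{path}: empty file")
    end = raw.find(b"end_header")
    if not raw.startswith(b"ply") or end < 0:
        raise ParseError(f"{path}: not a PLY file (missing 'ply'/'end_header')")
    nl = raw.find(b"\n", end)
    header = raw[:nl].decode("ascii", errors="replace").splitlines()
    body = raw[nl + 1:]

    fmt = None
    n_vertices = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    for lineno, line in enumerate(header[1:], start=2):
        tok = line.split()
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertices = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            if tok[1] == "list":
                raise ParseError(f"{path}:{lineno}: list property in vertex element unsupported")
            if tok[1] not in _PLY_TYPES:
                raise ParseError(f"{path}:{lineno}: unknown property type {tok[1]!r}")
            props.append((tok[1], tok[2]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise ParseError(f"{path}: unsupported PLY format {fmt!r}")
    if n_vertices is None:
        raise ParseError(f"{path}: header has no vertex element")
    if n_vertices == 0:
        raise EmptyCloudError(f"{path}: vertex count is zero")
    names = [name for _, name in props]
    for need in ("x", "y", "z"):
        if need not in names:
            raise ParseError(f"{path}: vertex element lacks property {need!r}")

    if fmt == "ascii":
        rows = []
        lines = body.decode("ascii", errors="replace").splitlines()
        if len([ln for ln in lines if ln.strip()]) < n_vertices:
            raise ParseError(f"{path}: expected {n_vertices} vertex records")
        for i, line in enumerate([ln for ln in lines if ln.strip()][:n_vertices]):
            vals = line.split()
            if len(vals) != len(props):
                raise ParseError(f"{path}: vertex record {i} has {len(vals)} fields, expected {len(props)}")
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise ParseError(f"{path}: vertex record {i}: {exc}") from None
        data = np.array(rows, dtype=np.float64)
    else:
        fmt_str = "<" + "".join(_PLY_TYPES[t][0] for t, _ in props)
        rec = struct.calcsize(fmt_str)
        if len(body) < rec * n_vertices:
            raise ParseError(
                f"{path}: binary body holds {len(body)} bytes, "
                f"need {rec * n_vertices} (at byte {nl + 1})"
            )
        data = np.array(
            [struct.unpack_from(fmt_str, body, i * rec) for i in range(n_vertices)],
            dtype=np.float64,
        )

    cols = {name: data[:, i] for i, name in enumerate(names)}
    points = np.column_stack([cols["x"], cols["y"], cols["z"]])
    normals = None
    if all(k in cols for k in ("nx", "ny", "nz")):
        normals = np.column_stack([cols["nx"], cols["ny"], cols["nz"]])
        norms = np.linalg.norm(normals, axis=1)
        normals = normals / np.where(norms > 0, norms, 1.0)[:, None]
    return PointCloud(points, normals)


def _write_ply(cloud: PointCloud, path: Path, binary: bool) -> None:
    has_n = cloud.normals is not None
    props = ["x", "y", "z"] + (["nx", "ny", "nz"] if has_n else [])
    header = ["ply",
              f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              "comment unit: cm",
              f"element vertex {len(cloud)}"]
    header += [f"property double {p}" for p in props]
    header += ["end_header"]
    data = cloud.points if not has_n else np.hstack([cloud.points, cloud.normals])
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(data, dtype="<f8").tobytes())
        else:
            np.savetxt(fh, data, fmt="%.17g")


# ---------------------------------------------------------------- PCD

def _read_pcd(path: Path) -> PointCloud:
    lines = path.read_text().splitlines()
    if not lines:
        raise EmptyCloudError(f"{path}: empty file")
    meta = {}
    data_start = None
    for i, line in enumerate(lines):
        tok = line.split()
        if not tok or tok[0] == "#":
            continue
        if tok[0] == "DATA":
            if tok[1] != "ascii":
                raise ParseError(f"{path}:{i + 1}: only DATA ascii is supported")
            data_start = i + 1
            break
        meta[tok[0]] = tok[1:]
    if data_start is None or "FIELDS" not in meta or "POINTS" not in meta:
        raise ParseError(f"{path}: missing FIELDS/POINTS/DATA header lines")
    fields = meta["FIELDS"]
    n = int(meta["POINTS"][0])
    if n == 0:
        raise EmptyCloudError(f"{path}: POINTS is zero")
    rows = []
    body = [ln for ln in lines[data_start:] if ln.strip()]
    if len(body) < n:
        raise ParseError(f"{path}: expected {n} data rows, found {len(body)}")
    for i, line in enumerate(body[:n]):
        vals = line.split()
        if len(vals) != len(fields):
            raise ParseError(f"{path}: data row {i} has {len(vals)} fields, expected {len(fields)}")
        try:
            rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise ParseError(f"{path}: data row {i}: {exc}") from None
    data = np.array(rows)
    cols = {f: data[:, i] for i, f in enumerate(fields)}
    for need in ("x", "y", "z"):
        if need not in cols:
            raise ParseError(f"{path}: FIELDS lacks {need!r}")
    points = np.column_stack([cols["x"], cols["y"], cols["z"]])
    normals = None
    nk = ("normal_x", "normal_y", "normal_z")
    if all(k in cols for k in nk):
        normals = np.column_stack([cols[k] for k in nk])
        norms = np.linalg.norm(normals, axis=1)
        normals = normals / np.where(norms > 0, norms, 1.0)[:, None]
    return PointCloud(points, normals)


def _write_pcd(cloud: PointCloud, path: Path) -> None:
    has_n = cloud.normals is not None
    fields = ["x", "y", "z"] + (["normal_x", "normal_y", "normal_z"] if has_n else [])
    n = len(cloud)
    header = [
        "# .PCD v0.7 - Point Cloud Data file format",
        "# unit: cm",
        "VERSION 0.7",
        f"FIELDS {' '.join(fields)}",
        f"SIZE {' '.join(['8'] * len(fields))}",
        f"TYPE {' '.join(['F'] * len(fields))}",
        f"COUNT {' '.join(['1'] * len(fields))}",
        f"WIDTH {n}",
        "HEIGHT 1",
        "VIEWPOINT 0 0 0 1 0 0 0",
        f"POINTS {n}",
        "DATA ascii",
    ]
    data = cloud.points if not has_n else np.hstack([cloud.points, cloud.normals])
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, data, fmt="%.17g")


# ---------------------------------------------------------------- XYZ

def _read_xyz(path: Path) -> PointCloud:
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            vals = s.split()
            if len(vals) not in (3, 6):
                raise ParseError(f"{path}:{lineno}: expected 3 or 6 columns, got {len(vals)}")
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise ParseError(f"{path}:{lineno}: inconsistent column count")
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise EmptyCloudError(f"{path}: no data rows")
    data = np.array(rows)
    normals = data[:, 3:6] if data.shape[1] == 6 else None
    return PointCloud(data[:, :3], normals)


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    data = cloud.points if cloud.normals is None else np.hstack([cloud.points, cloud.normals])
    with open(path, "w") as fh:
        fh.write("# unit: cm\n")
        np.savetxt(fh, data, fmt="%.17g")
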