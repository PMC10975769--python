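"""Point-cloud and mesh file I/O.

Supported cloud dialects:

* ``ply`` — ascii and binary_little_endian read; ascii write.  Colors are
  uchar ``red/green/blue`` (scaled to [0, 1] in memory), normals are float
  ``nx/ny/nz``.
* ``pcd`` — ascii, with either a packed float ``rgb`` field (the common
  convention) or separate ``r g b`` fields on read; packed ``rgb`` on write.
* ``xyz`` — whitespace text, ``x y z [r g b]`` per line.  Colors written
  normalized to [0, 1]; on read, any channel above 1 is taken as 8-bit and
  divided by 255.

Mesh export (OBJ, ascii PLY) is delegated to :mod:`trimesh`.
"""

from __future__ import annotations

import os

import numpy as np
import trimesh

from .cloud import PointCloud, TriangleMesh

_PLY_TYPES = {
    "char": "i1", "uchar": "u1", "int8": "i1", "uint8": "u1",
    "short": "i2", "ushort": "u2", "int16": "i2", "uint16": "u2",
    "int": "i4", "uint": "u4", "int32": "i4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


class PointCloudParseError(ValueError):
    """Malformed record in a point-cloud file."""


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("ply", "pcd", "xyz", "txt"):
        return "xyz" if ext == "txt" else ext
    raise ValueError(f"cannot infer point-cloud format from {path!r}; pass format=")


def read_point_cloud(path: str, format: str | None = None) -> PointCloud:
    """Read a point cloud, preserving file point order.

    Colors are populated iff present in the file.
    """
    fmt = _infer_format(path, format)
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "pcd":
        return _read_pcd(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unsupported format {fmt!r}")


def write_point_cloud(cloud: PointCloud, path: str, format: str | None = None) -> None:
    """Write a point cloud; the file round-trips through :func:`read_point_cloud`."""
    fmt = _infer_format(path, format)
    if fmt == "ply":
        _write_ply(cloud, path)
    elif fmt == "pcd":
        _write_pcd(cloud, path)
    elif fmt == "xyz":
        _write_xyz(cloud, path)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


# ---------------------------------------------------------------- PLY


def _read_ply(path: str) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise PointCloudParseError(f"{path}: not a PLY file (bad magic {magic!r})")
        fmt = None
        elements: list[tuple[str, int, list[tuple[str, str]]]] = []
        while True:
            line = fh.readline()
            if not line:
                raise PointCloudParseError(f"{path}: unexpected EOF in header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if tokens[1] == "list":
                    elements[-1][2].append((tokens[-1], f"list:{tokens[2]}:{tokens[3]}"))
                else:
                    elements[-1][2].append((tokens[-1], tokens[1]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise PointCloudParseError(f"{path}: unsupported PLY format {fmt!r}")
        vertex = None
        for name, count, props in elements:
            if name == "vertex":
                vertex = (count, props)
                break
        if vertex is None:
            raise PointCloudParseError(f"{path}: no vertex element")
        count, props = vertex
        if any(t.startswith("list:") for _, t in props):
            raise PointCloudParseError(f"{path}: list property on vertex element unsupported")
        dtype = np.dtype([(n, "<" + _PLY_TYPES[t]) for n, t in props])
        if fmt == "binary_little_endian":
            if elements[0][0] != "vertex":
                raise PointCloudParseError(f"{path}: vertex must be the first element for binary read")
            data = np.frombuffer(fh.read(dtype.itemsize * count), dtype=dtype, count=count)
        else:
            rows = []
            while len(rows) < count:
                line = fh.readline()
                if not line:
                    raise PointCloudParseError(f"{path}: vertex record {len(rows) + 1} missing")
                if line.strip():
                    rows.append(line.split())
            try:
                data = np.array([tuple(r[: len(props)]) for r in rows], dtype=dtype)
            except ValueError as exc:
                raise PointCloudParseError(f"{path}: malformed vertex record: {exc}") from exc
    names = data.dtype.names
    for axis in ("x", "y", "z"):
        if axis not in names:
            raise PointCloudParseError(f"{path}: vertex element lacks {axis!r}")
    pts = np.column_stack([data["x"], data["y"], data["z"]]).astype(float)
    colors = None
    if all(c in names for c in ("red", "green", "blue")):
        cols = np.column_stack([data["red"], data["green"], data["blue"]]).astype(float)
        if data.dtype["red"].kind == "u":
            cols /= 255.0
        colors = np.clip(cols, 0.0, 1.0)
    normals = None
    if all(c in names for c in ("nx", "ny", "nz")):
        normals = np.column_stack([data["nx"], data["ny"], data["nz"]]).astype(float)
        norms = np.linalg.norm(normals, axis=1)
        normals = normals / np.where(norms > 0, norms, 1.0)[:, None]
    return PointCloud(pts, colors, normals)


def _write_ply(cloud: PointCloud, path: str) -> None:
    n = len(cloud)
    header = ["ply", "format ascii 1.0", f"element vertex {n}"]
    # double precision so coordinates survive a write/read cycle to 1e-6 mm
    header += [f"property double {a}" for a in ("x", "y", "z")]
    if cloud.normals is not None:
        header += [f"property double {a}" for a in ("nx", "ny", "nz")]
    if cloud.colors is not None:
        header += [f"property uchar {c}" for c in ("red", "green", "blue")]
    header += ["end_header"]
    cols = [cloud.points]
    fmt = ["%.10g"] * 3
    if cloud.normals is not None:
        cols.append(cloud.normals)
        fmt += ["%.10g"] * 3
    if cloud.colors is not None:
        cols.append(np.rint(cloud.colors * 255.0))
        fmt += ["%d"] * 3
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        if n:
            np.savetxt(fh, np.column_stack(cols), fmt=" ".join(fmt))


# ---------------------------------------------------------------- PCD


def _read_pcd(path: str) -> PointCloud:
    fields: list[str] = []
    count = 0
    with open(path, "r") as fh:
        for line in fh:
            tokens = line.split()
            if not tokens or tokens[0] == "#":
                continue
            key = tokens[0].upper()
            if key == "FIELDS":
                fields = tokens[1:]
            elif key == "POINTS":
                count = int(tokens[1])
            elif key == "DATA":
                if tokens[1] != "ascii":
                    raise PointCloudParseError(f"{path}: only ascii PCD supported")
                break
        rows = [ln.split() for ln in fh if ln.strip()]
    if len(rows) != count:
        raise PointCloudParseError(f"{path}: POINTS says {count}, found {len(rows)} records")
    try:
        data = np.array(rows, dtype=float) if rows else np.zeros((0, max(len(fields), 3)))
    except ValueError as exc:
        raise PointCloudParseError(f"{path}: malformed record: {exc}") from exc
    idx = {f: i for i, f in enumerate(fields)}
    for axis in ("x", "y", "z"):
        if axis not in idx:
            raise PointCloudParseError(f"{path}: missing field {axis!r}")
    pts = data[:, [idx["x"], idx["y"], idx["z"]]]
    colors = None
    if "rgb" in idx and len(data):
        packed = data[:, idx["rgb"]].astype(np.float32).view(np.uint32)
        colors = (
            np.column_stack([(packed >> 16) & 255, (packed >> 8) & 255, packed & 255]) / 255.0
        )
    elif all(c in idx for c in ("r", "g", "b")):
        colors = data[:, [idx["r"], idx["g"], idx["b"]]]
        if len(colors) and colors.max() > 1.0:
            colors = colors / 255.0
    normals = None
    if all(c in idx for c in ("normal_x", "normal_y", "normal_z")):
        normals = data[:, [idx["normal_x"], idx["normal_y"], idx["normal_z"]]]
    return PointCloud(pts, colors, normals)


def _write_pcd(cloud: PointCloud, path: str) -> None:
    n = len(cloud)
    fields = ["x", "y", "z"]
    cols = [cloud.points]
    fmt = ["%.10g"] * 3
    if cloud.normals is not None:
        fields += ["normal_x", "normal_y", "normal_z"]
        cols.append(cloud.normals)
        fmt += ["%.10g"] * 3
    if cloud.colors is not None:
        fields.append("rgb")
        rgb8 = np.rint(cloud.colors * 255.0).astype(np.uint32)
        packed = (rgb8[:, 0] << 16) | (rgb8[:, 1] << 8) | rgb8[:, 2]
        cols.append(packed.view(np.float32).astype(np.float64)[:, None])
        fmt += ["%.9g"]
    sizes = " ".join(["4"] * len(fields))
    types = " ".join(["F"] * len(fields))
    counts = " ".join(["1"] * len(fields))
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\n"
        "VERSION 0.7\n"
        f"FIELDS {' '.join(fields)}\n"
        f"SIZE {sizes}\nTYPE {types}\nCOUNT {counts}\n"
        f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\n"
        f"POINTS {n}\nDATA ascii\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        if n:
            np.savetxt(fh, np.column_stack(cols), fmt=" ".join(fmt))


# ---------------------------------------------------------------- XYZ


def _read_xyz(path: str) -> PointCloud:
    rows = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) not in (3, 6):
                raise PointCloudParseError(
                    f"{path}:{lineno}: expected 3 or 6 columns, got {len(tokens)}"
                )
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise PointCloudParseError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        return PointCloud(np.zeros((0, 3)))
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise PointCloudParseError(f"{path}: inconsistent column counts {sorted(widths)}")
    data = np.array(rows, dtype=float)
    colors = None
    if data.shape[1] == 6:
        colors = data[:, 3:6]
        if colors.max() > 1.0:
            colors = colors / 255.0
    return PointCloud(data[:, :3], colors)


def _write_xyz(cloud: PointCloud, path: str) -> None:
    if cloud.colors is not None:
        data = np.column_stack([cloud.points, cloud.colors])
    else:
        data = cloud.points
    np.savetxt(path, data, fmt="%.10g")


# ---------------------------------------------------------------- meshes


def write_mesh(mesh: TriangleMesh, path: str) -> None:
    """Export a triangle mesh as OBJ or ascii PLY (by file extension)."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".obj":
        tm.export(path)
    elif ext == ".ply":
        tm.export(path, encoding="ascii")
    else:
        raise ValueError(f"unsupported mesh format {ext!r} (use .obj or .ply)")


def read_mesh(path: str) -> TriangleMesh:
    tm = trimesh.load(path, force="mesh", process=False)
    return TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))
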