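"""Minimal PLY reader/writer for triangulated surfaces.

Supports the two dialects used for segmented bone meshes: ``ascii 1.0`` and
``binary_little_endian 1.0``. Coordinates are stored as float64 so a binary
round trip is bit-exact; an optional per-vertex scalar property can ride
along (e.g. a surface-distance or curvature field).
"""

from __future__ import annotations

import struct
import warnings
from pathlib import Path

import numpy as np

_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


class PlyFormatError(ValueError):
    """Raised when a PLY header or body cannot be parsed."""


def _parse_header(stream) -> tuple[str, list, int]:
    magic = stream.readline().strip()
    if magic != b"ply":
        raise PlyFormatError("not a PLY file (missing 'ply' magic)")
    fmt = None
    elements = []  # list of (name, count, [(prop_name, dtype, is_list, count_dtype)])
    while True:
        raw = stream.readline()
        if not raw:
            raise PlyFormatError("unexpected EOF in PLY header")
        line = raw.decode("ascii", errors="replace").strip()
        if not line or line.startswith("comment") or line.startswith("obj_info"):
            continue
        tokens = line.split()
        if tokens[0] == "format":
            if tokens[1] not in ("ascii", "binary_little_endian"):
                raise PlyFormatError(f"unsupported PLY format {tokens[1]!r}")
            fmt = tokens[1]
        elif tokens[0] == "element":
            elements.append((tokens[1], int(tokens[2]), []))
        elif tokens[0] == "property":
            if not elements:
                raise PlyFormatError("property before any element")
            if tokens[1] == "list":
                count_t, item_t, name = tokens[2], tokens[3], tokens[4]
                elements[-1][2].append((name, _PLY_TYPES[item_t], True, _PLY_TYPES[count_t]))
            else:
                elements[-1][2].append((tokens[2], _PLY_TYPES[tokens[1]], False, None))
        elif tokens[0] == "end_header":
            break
        else:
            raise PlyFormatError(f"unrecognized header line {line!r}")
    if fmt is None:
        raise PlyFormatError("PLY header missing 'format' line")
    return fmt, elements, stream.tell()


def read_ply(path, triangulate: bool = False
             ) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Read a triangulated PLY file.

    Returns ``(vertices, faces, scalars)`` where vertices is float64 (n, 3),
    faces is int64 (m, 3) and scalars maps extra per-vertex property names to
    float64 arrays. Non-triangular faces raise :class:`PlyFormatError` unless
    ``triangulate`` is set, in which case polygons are fan-triangulated.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        fmt, elements, _ = _parse_header(fh)
        data = {}
        if fmt == "ascii":
            tokens = fh.read().split()
            pos = 0
            for name, count, props in elements:
                if any(is_list for _, _, is_list, _ in props):
                    rows = []
                    for _ in range(count):
                        n_items = int(tokens[pos]); pos += 1
                        rows.append([float(t) for t in tokens[pos:pos + n_items]])
                        pos += n_items
                    data[name] = rows
                else:
                    ncol = len(props)
                    flat = np.array(tokens[pos:pos + count * ncol], dtype=np.float64)
                    pos += count * ncol
                    data[name] = {p[0]: flat.reshape(count, ncol)[:, i]
                                  for i, p in enumerate(props)}
        else:  # binary little-endian
            for name, count, props in elements:
                if any(is_list for _, _, is_list, _ in props):
                    rows = []
                    for _ in range(count):
                        _, item_dt, _, count_dt = props[0]
                        n_items = int(np.frombuffer(
                            fh.read(np.dtype(count_dt).itemsize), dtype="<" + count_dt)[0])
                        rows.append(np.frombuffer(
                            fh.read(n_items * np.dtype(item_dt).itemsize),
                            dtype="<" + item_dt).astype(np.float64))
                    data[name] = rows
                else:
                    dt = np.dtype([(p[0], "<" + p[1]) for p in props])
                    arr = np.frombuffer(fh.read(count * dt.itemsize), dtype=dt)
                    data[name] = {p[0]: arr[p[0]].astype(np.float64) for p in props}

    if "vertex" not in data:
        raise PlyFormatError("PLY file has no vertex element")
    vd = data["vertex"]
    try:
        vertices = np.column_stack([vd["x"], vd["y"], vd["z"]]).astype(np.float64)
    except KeyError as exc:
        raise PlyFormatError("vertex element missing x/y/z") from exc
    scalars = {k: np.asarray(v, dtype=np.float64) for k, v in vd.items()
               if k not in ("x", "y", "z", "nx", "ny", "nz")}

    face_rows = data.get("face", [])
    faces = np.zeros((0, 3), dtype=np.int64)
    if len(face_rows):
        lengths = {len(r) for r in face_rows}
        if lengths == {3}:
            faces = np.array(face_rows, dtype=np.int64)
        elif triangulate:
            tris = []
            for row in face_rows:
                row = [int(v) for v in row]
                for k in range(1, len(row) - 1):
                    tris.append((row[0], row[k], row[k + 1]))
            faces = np.array(tris, dtype=np.int64)
        else:
            raise PlyFormatError(
                f"non-triangular faces present (sizes {sorted(lengths)}) "
                "and triangulation is disabled")
    if faces.size:
        referenced = np.zeros(len(vertices), dtype=bool)
        referenced[faces.ravel()] = True
        if not referenced.all():
            warnings.warn(
                f"{path.name}: {int((~referenced).sum())} vertices not referenced "
                "by any face; retained", stacklevel=2)
    return vertices, faces, scalars


def write_ply(path, vertices, faces, dialect="binary_le",
              scalars: dict[str, np.ndarray] | None = None) -> None:
    """Write a triangulated mesh as PLY (``ascii`` or ``binary_le``).

    Coordinates and scalars are written as float64 (``double``), so the
    binary dialect round-trips bit-exactly.
    """
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    if len(vertices) == 0:
        raise ValueError("refusing to write an empty mesh")
    scalars = scalars or {}
    for name, vals in scalars.items():
        if len(vals) != len(vertices):
            raise ValueError(f"scalar field {name!r} length mismatch")

    header = ["ply"]
    header.append("format ascii 1.0" if dialect == "ascii"
                  else "format binary_little_endian 1.0")
    if dialect not in ("ascii", "binary_le"):
        raise ValueError(f"unknown PLY dialect {dialect!r}")
    header.append(f"element vertex {len(vertices)}")
    header += ["property double x", "property double y", "property double z"]
    for name in scalars:
        header.append(f"property double {name}")
    header.append(f"element face {len(faces)}")
    header.append("property list uchar int vertex_indices")
    header.append("end_header")

    scalar_cols = [np.asarray(scalars[name], dtype=np.float64) for name in scalars]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if dialect == "ascii":
            cols = [vertices] + [c[:, None] for c in scalar_cols]
            block = np.hstack(cols)
            lines = ["\t".join(f"{x:.17g}" for x in row) for row in block]
            fh.write(("\n".join(lines) + "\n").encode("ascii"))
            flines = ["3 " + " ".join(str(i) for i in row) for row in faces]
            if len(flines):
                fh.write(("\n".join(flines) + "\n").encode("ascii"))
        else:
            dt = np.dtype([("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
                          + [(n, "<f8") for n in scalars])
            rec = np.empty(len(vertices), dtype=dt)
            rec["x"], rec["y"], rec["z"] = vertices.T
            for name, col in zip(scalars, scalar_cols):
                rec[name] = col
            fh.write(rec.tobytes())
            for row in faces:
                fh.write(struct.pack("<B3i", 3, *row))
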