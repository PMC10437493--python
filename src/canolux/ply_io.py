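"""PLY reading/writing for labelled point clouds and triangle meshes.

Supports ascii and binary_little_endian encodings.  Integer properties
``plant_id``, ``organ`` and ``leaf_id`` on both vertices and faces carry the
pipeline's provenance labels and round-trip losslessly; unknown extra
properties are read and ignored.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np

from .geometry import PointCloud, TriangleMesh

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

_LABELS = ("plant_id", "organ", "leaf_id")


class PlyFormatError(ValueError):
    """Raised for malformed PLY input, with header/element context."""


class _Element:
    def __init__(self, name: str, count: int):
        self.name = name
        self.count = count
        self.properties: list[tuple] = []  # (name, dtype) or (name, "list", ct, it)


def _parse_header(fh) -> tuple[list[_Element], str, list[str]]:
    line = fh.readline()
    if line.strip() != b"ply":
        raise PlyFormatError("not a PLY file: missing 'ply' magic line")
    fmt = None
    elements: list[_Element] = []
    comments: list[str] = []
    while True:
        raw = fh.readline()
        if not raw:
            raise PlyFormatError("unexpected end of file inside PLY header")
        line = raw.decode("ascii", "replace").strip()
        if not line:
            continue
        tok = line.split()
        if tok[0] == "comment":
            comments.append(line[len("comment "):] if len(line) > 8 else "")
        elif tok[0] == "format":
            if tok[1] not in ("ascii", "binary_little_endian"):
                raise PlyFormatError(f"unsupported PLY format '{tok[1]}'")
            fmt = tok[1]
        elif tok[0] == "element":
            if len(tok) != 3:
                raise PlyFormatError(f"malformed element line: '{line}'")
            try:
                elements.append(_Element(tok[1], int(tok[2])))
            except ValueError:
                raise PlyFormatError(f"bad element count in '{line}'") from None
        elif tok[0] == "property":
            if not elements:
                raise PlyFormatError(f"property before any element: '{line}'")
            el = elements[-1]
            if tok[1] == "list":
                if len(tok) != 5 or tok[2] not in _PLY_TYPES or tok[3] not in _PLY_TYPES:
                    raise PlyFormatError(
                        f"malformed list property in element '{el.name}': '{line}'"
                    )
                el.properties.append((tok[4], "list", _PLY_TYPES[tok[2]], _PLY_TYPES[tok[3]]))
            else:
                if len(tok) != 3 or tok[1] not in _PLY_TYPES:
                    raise PlyFormatError(
                        f"malformed property in element '{el.name}': '{line}'"
                    )
                el.properties.append((tok[2], _PLY_TYPES[tok[1]]))
        elif tok[0] == "end_header":
            break
        else:
            raise PlyFormatError(f"unrecognised header line: '{line}'")
    if fmt is None:
        raise PlyFormatError("PLY header has no 'format' line")
    return elements, fmt, comments


def _read_ascii_element(fh, el: _Element) -> dict[str, np.ndarray]:
    scalar = [p for p in el.properties if p[1] != "list"]
    lists = [p for p in el.properties if p[1] == "list"]
    cols: dict[str, list] = {p[0]: [] for p in el.properties}
    for i in range(el.count):
        raw = fh.readline()
        if not raw:
            raise PlyFormatError(f"element '{el.name}': expected {el.count} rows, file ended at row {i}")
        tok = raw.split()
        j = 0
        try:
            for p in el.properties:
                if p[1] == "list":
                    n = int(tok[j]); j += 1
                    cols[p[0]].append([float(t) for t in tok[j:j + n]])
                    j += n
                else:
                    cols[p[0]].append(float(tok[j])); j += 1
        except (IndexError, ValueError):
            raise PlyFormatError(
                f"element '{el.name}' row {i}: cannot parse '{raw.decode('ascii', 'replace').strip()}'"
            ) from None
    out = {}
    for name, dt in scalar:
        out[name] = np.asarray(cols[name], dtype=dt)
    for name, _, _, it in lists:
        out[name] = [np.asarray(v, dtype=it) for v in cols[name]]
    return out


def _read_binary_element(fh, el: _Element) -> dict[str, np.ndarray]:
    if any(p[1] == "list" for p in el.properties):
        # variable-length rows: parse sequentially
        out: dict[str, list] = {p[0]: [] for p in el.properties}
        for i in range(el.count):
            for p in el.properties:
                if p[1] == "list":
                    cnt = np.frombuffer(fh.read(np.dtype(p[2]).itemsize), dtype="<" + p[2])
                    if cnt.size != 1:
                        raise PlyFormatError(f"element '{el.name}' row {i}: truncated list count")
                    n = int(cnt[0])
                    item = np.dtype(p[3]).itemsize
                    buf = fh.read(n * item)
                    if len(buf) != n * item:
                        raise PlyFormatError(f"element '{el.name}' row {i}: truncated list data")
                    out[p[0]].append(np.frombuffer(buf, dtype="<" + p[3]))
                else:
                    item = np.dtype(p[1]).itemsize
                    buf = fh.read(item)
                    if len(buf) != item:
                        raise PlyFormatError(f"element '{el.name}' row {i}: truncated data")
                    out[p[0]].append(np.frombuffer(buf, dtype="<" + p[1])[0])
        return {
            k: (v if isinstance(v[0], np.ndarray) else np.asarray(v))
            if v else np.asarray(v)
            for k, v in out.items()
        }
    dt = np.dtype([(p[0], "<" + p[1]) for p in el.properties])
    buf = fh.read(dt.itemsize * el.count)
    if len(buf) != dt.itemsize * el.count:
        raise PlyFormatError(f"element '{el.name}': truncated binary data")
    rec = np.frombuffer(buf, dtype=dt)
    return {p[0]: rec[p[0]].copy() for p in el.properties}


def read_ply(path) -> PointCloud | TriangleMesh:
    """Read a PLY file; returns a TriangleMesh if it has faces, else a PointCloud."""
    path = Path(path)
    with open(path, "rb") as fh:
        elements, fmt, _ = _parse_header(fh)
        data: dict[str, dict] = {}
        for el in elements:
            if fmt == "ascii":
                data[el.name] = _read_ascii_element(fh, el)
            else:
                data[el.name] = _read_binary_element(fh, el)

    if "vertex" not in data:
        raise PlyFormatError("PLY file has no 'vertex' element")
    v = data["vertex"]
    for axis in "xyz":
        if axis not in v:
            raise PlyFormatError(f"vertex element lacks '{axis}' property")
    xyz = np.column_stack([v["x"], v["y"], v["z"]]).astype(np.float64)
    vlab = {k: v[k].astype(np.int32) for k in _LABELS if k in v}

    face_el = data.get("face")
    if face_el is None:
        return PointCloud(xyz, **vlab)

    idx_key = "vertex_indices" if "vertex_indices" in face_el else "vertex_index"
    if idx_key not in face_el:
        raise PlyFormatError("face element lacks 'vertex_indices' property")
    rows = face_el[idx_key]
    faces = []
    for i, r in enumerate(rows):
        r = np.asarray(r, dtype=np.int64)
        if len(r) == 3:
            faces.append(r)
        elif len(r) > 3:  # fan-triangulate polygons
            for k in range(1, len(r) - 1):
                faces.append(np.array([r[0], r[k], r[k + 1]], dtype=np.int64))
        else:
            raise PlyFormatError(f"face {i} has {len(r)} vertices (< 3)")
    faces = np.asarray(faces, dtype=np.int64) if faces else np.zeros((0, 3), np.int64)
    flab = {}
    if len(faces) == len(rows):  # labels only survive when no fan-splitting happened
        flab = {k: np.asarray(face_el[k], dtype=np.int32) for k in _LABELS if k in face_el}
    return TriangleMesh(xyz, faces, **flab)


def _has_labels(arr: np.ndarray) -> bool:
    return bool(np.any(arr != -1))


def write_ply(obj: PointCloud | TriangleMesh, path, binary: bool = False,
              comments: tuple[str, ...] = ()) -> None:
    """Write a labelled cloud or mesh as ascii (default) or binary_little_endian PLY."""
    path = Path(path)
    is_mesh = isinstance(obj, TriangleMesh)
    xyz = obj.vertices if is_mesh else obj.xyz
    header = ["ply", "format binary_little_endian 1.0" if binary else "format ascii 1.0"]
    header += [f"comment {c}" for c in comments]
    header.append(f"element vertex {len(xyz)}")
    header += [f"property double {ax}" for ax in "xyz"]
    vlabels = []
    if not is_mesh:
        for name in _LABELS:
            arr = getattr(obj, name)
            if _has_labels(arr):
                vlabels.append(name)
                header.append(f"property int {name}")
    flabels = []
    if is_mesh:
        header.append(f"element face {obj.n_faces}")
        header.append("property list uchar int vertex_indices")
        for name in _LABELS:
            arr = getattr(obj, name)
            if _has_labels(arr):
                flabels.append(name)
                header.append(f"property int {name}")
    header.append("end_header")

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            vdt = [(ax, "<f8") for ax in "xyz"] + [(n, "<i4") for n in vlabels]
            rec = np.empty(len(xyz), dtype=vdt)
            rec["x"], rec["y"], rec["z"] = xyz[:, 0], xyz[:, 1], xyz[:, 2]
            for n in vlabels:
                rec[n] = getattr(obj, n)
            fh.write(rec.tobytes())
            if is_mesh:
                fdt = [("n", "u1"), ("i0", "<i4"), ("i1", "<i4"), ("i2", "<i4")]
                fdt += [(n, "<i4") for n in flabels]
                rec = np.empty(obj.n_faces, dtype=fdt)
                rec["n"] = 3
                rec["i0"], rec["i1"], rec["i2"] = (
                    obj.faces[:, 0], obj.faces[:, 1], obj.faces[:, 2])
                for n in flabels:
                    rec[n] = getattr(obj, n)
                fh.write(rec.tobytes())
        else:
            buf = io.StringIO()
            for i in range(len(xyz)):
                row = f"{xyz[i, 0]:.17g} {xyz[i, 1]:.17g} {xyz[i, 2]:.17g}"
                for n in vlabels:
                    row += f" {int(getattr(obj, n)[i])}"
                buf.write(row + "\n")
            if is_mesh:
                for i in range(obj.n_faces):
                    row = f"3 {obj.faces[i, 0]} {obj.faces[i, 1]} {obj.faces[i, 2]}"
                    for n in flabels:
                        row += f" {int(getattr(obj, n)[i])}"
                    buf.write(row + "\n")
            fh.write(buf.getvalue().encode("ascii"))
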