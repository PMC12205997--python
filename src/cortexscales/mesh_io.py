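"""Surface and label file I/O.

Two surface dialects are supported:

* the FreeSurfer binary triangle-surface format (3-byte magic
  ``0xFF 0xFF 0xFE``, a creation-comment line terminated by two newlines,
  big-endian vertex/face counts, float32 vertices, int32 faces, 0-based);
* ASCII PLY 1.0 (delegated to trimesh).

Vertex labels come either from FreeSurfer ``.annot`` files (big-endian
(vertex, packed-RGB) pairs plus a colortable) or from a plain CSV table with
header ``vertex,label``.  Readers reject files that violate the declared
dialect instead of guessing.
"""

from __future__ import annotations

import io
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import MeshValidationError, TriangleMesh, VertexLabels

_TRIANGLE_MAGIC = b"\xff\xff\xfe"


class SurfaceFormatError(ValueError):
    """File does not match the declared surface/label dialect."""


class SurfaceParseError(ValueError):
    """File matches the dialect magic but is truncated or inconsistent."""


# ----------------------------------------------------------------------
# FreeSurfer binary triangle surfaces
# ----------------------------------------------------------------------

def _read_exact(fh, n: int) -> bytes:
    buf = fh.read(n)
    if len(buf) != n:
        raise SurfaceParseError(f"truncated file: wanted {n} bytes, got {len(buf)}")
    return buf


def _read_freesurfer(path: Path) -> TriangleMesh:
    with open(path, "rb") as fh:
        magic = fh.read(3)
        if magic != _TRIANGLE_MAGIC:
            raise SurfaceFormatError(
                f"{path}: magic {magic!r} is not a triangle-surface file"
            )
        # creation comment, terminated by two newlines
        comment = b""
        while not comment.endswith(b"\n\n"):
            c = fh.read(1)
            if not c:
                raise SurfaceParseError(f"{path}: unterminated creation comment")
            comment += c
        nv, nf = struct.unpack(">ii", _read_exact(fh, 8))
        if nv < 0 or nf < 0:
            raise SurfaceParseError(f"{path}: negative counts ({nv}, {nf})")
        verts = np.frombuffer(_read_exact(fh, 12 * nv), dtype=">f4").reshape(nv, 3)
        faces = np.frombuffer(_read_exact(fh, 12 * nf), dtype=">i4").reshape(nf, 3)
    if nf and (faces.min() < 0 or faces.max() >= nv):
        raise MeshValidationError(f"{path}: face index out of range")
    return TriangleMesh(verts.astype(np.float64), faces.astype(np.int64))


def _write_freesurfer(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "wb") as fh:
        fh.write(_TRIANGLE_MAGIC)
        fh.write(b"created by cortexscales\n\n")
        fh.write(struct.pack(">ii", mesh.n_vertices, mesh.n_faces))
        fh.write(mesh.vertices.astype(">f4").tobytes())
        fh.write(mesh.faces.astype(">i4").tobytes())


# ----------------------------------------------------------------------
# PLY (ASCII 1.0) via trimesh
# ----------------------------------------------------------------------

def _read_ply(path: Path) -> TriangleMesh:
    import trimesh

    with open(path, "rb") as fh:
        head = fh.read(3)
    if head != b"ply":
        raise SurfaceFormatError(f"{path}: not a PLY file")
    tm = trimesh.load(str(path), file_type="ply", process=False)
    faces = np.asarray(tm.faces)
    if faces.shape[1] != 3:
        raise SurfaceParseError(f"{path}: non-triangular PLY faces")
    return TriangleMesh(np.asarray(tm.vertices, dtype=np.float64), faces)


def _write_ply(mesh: TriangleMesh, path: Path) -> None:
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    path.write_bytes(trimesh.exchange.ply.export_ply(tm, encoding="ascii"))


# ----------------------------------------------------------------------
# public surface API
# ----------------------------------------------------------------------

_FORMATS = ("freesurfer", "ply")


def read_surface(path, fmt: str = "freesurfer") -> TriangleMesh:
    """Read a triangle mesh; coordinates pass through unchanged (mm)."""
    path = Path(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    return _read_freesurfer(path) if fmt == "freesurfer" else _read_ply(path)


def write_surface(mesh: TriangleMesh, path, fmt: str = "freesurfer") -> None:
    """Write a triangle mesh readable by :func:`read_surface`."""
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {_FORMATS}")
    mesh.validate()
    if mesh.n_faces == 0:
        raise MeshValidationError("refusing to write a mesh with no faces")
    path = Path(path)
    if fmt == "freesurfer":
        _write_freesurfer(mesh, path)
    else:
        _write_ply(mesh, path)


# ----------------------------------------------------------------------
# vertex labels: .annot and CSV
# ----------------------------------------------------------------------

def _code_rgb(code: int) -> tuple[int, int, int]:
    # Deterministic distinct colours for small code sets.
    return (code * 53 + 20) % 256, (code * 101 + 40) % 256, (code * 173 + 60) % 256


def write_vertex_labels(labels: VertexLabels, path, fmt: str = "annot") -> None:
    """Write labels as FreeSurfer .annot (old-style colortable) or CSV."""
    path = Path(path)
    if fmt == "csv":
        pd.DataFrame(
            {
                "vertex": np.arange(len(labels.labels)),
                "label": labels.labels,
                "name": [labels.name_map[int(c)] for c in labels.labels],
            }
        ).to_csv(path, index=False)
        return
    if fmt != "annot":
        raise ValueError(f"unknown label format {fmt!r}")
    codes = sorted(labels.name_map)
    buf = io.BytesIO()
    n = len(labels.labels)
    buf.write(struct.pack(">i", n))
    packed = np.empty(n, dtype=">i4")
    for code in codes:
        r, g, b = _code_rgb(code)
        packed[labels.labels == code] = r + (g << 8) + (b << 16)
    pairs = np.empty((n, 2), dtype=">i4")
    pairs[:, 0] = np.arange(n)
    pairs[:, 1] = packed
    buf.write(pairs.tobytes())
    buf.write(struct.pack(">i", 1))  # TAG_OLD_COLORTABLE
    buf.write(struct.pack(">i", len(codes)))
    fname = b"cortexscales.ctab"
    buf.write(struct.pack(">i", len(fname)) + fname)
    for code in codes:
        name = labels.name_map[code].encode()
        r, g, b = _code_rgb(code)
        buf.write(struct.pack(">i", len(name)) + name)
        buf.write(struct.pack(">iiii", r, g, b, 0))
    path.write_bytes(buf.getvalue())


def _read_annot(path: Path) -> VertexLabels:
    with open(path, "rb") as fh:
        (n,) = struct.unpack(">i", _read_exact(fh, 4))
        if n < 0:
            raise SurfaceParseError(f"{path}: negative vertex count")
        pairs = np.frombuffer(_read_exact(fh, 8 * n), dtype=">i4").reshape(n, 2)
        (tag,) = struct.unpack(">i", _read_exact(fh, 4))
        if tag != 1:
            raise SurfaceParseError(f"{path}: missing colortable tag")
        (n_entries,) = struct.unpack(">i", _read_exact(fh, 4))
        if n_entries <= 0:
            raise SurfaceParseError(f"{path}: only old-style positive-count colortables supported")
        (ln,) = struct.unpack(">i", _read_exact(fh, 4))
        _read_exact(fh, ln)  # colortable filename, unused
        packed_to_code: dict[int, int] = {}
        name_map: dict[int, str] = {}
        for code in range(n_entries):
            (ln,) = struct.unpack(">i", _read_exact(fh, 4))
            name = _read_exact(fh, ln).decode()
            r, g, b, _a = struct.unpack(">iiii", _read_exact(fh, 16))
            packed_to_code[r + (g << 8) + (b << 16)] = code
            name_map[code] = name
    labels = np.empty(n, dtype=np.int64)
    order = pairs[:, 0].astype(np.int64)
    if order.min() < 0 or order.max() >= n or len(np.unique(order)) != n:
        raise SurfaceParseError(f"{path}: bad vertex indices in annot pairs")
    for packed in np.unique(pairs[:, 1]):
        if int(packed) not in packed_to_code:
            raise MeshValidationError(f"{path}: annotation value {packed} not in colortable")
    codes = np.array([packed_to_code[int(p)] for p in pairs[:, 1]], dtype=np.int64)
    labels[order] = codes
    return VertexLabels(labels, name_map)


def read_vertex_labels(path, fmt: str, mesh: TriangleMesh) -> VertexLabels:
    """Read per-vertex labels aligned to ``mesh`` vertex order."""
    path = Path(path)
    if fmt == "annot":
        out = _read_annot(path)
    elif fmt == "csv":
        df = pd.read_csv(path)
        if not {"vertex", "label"} <= set(df.columns):
            raise SurfaceFormatError(f"{path}: CSV must have 'vertex,label' header")
        labels = np.full(len(df), -1, dtype=np.int64)
        idx = df["vertex"].to_numpy(dtype=np.int64)
        if len(df) and (idx.min() < 0 or len(np.unique(idx)) != len(df)):
            raise SurfaceParseError(f"{path}: bad or duplicate vertex indices")
        if len(df) and idx.max() >= len(df):
            raise MeshValidationError(f"{path}: vertex index exceeds row count")
        labels[idx] = df["label"].to_numpy(dtype=np.int64)
        if "name" in df.columns:
            name_map = dict(
                df.drop_duplicates("label")[["label", "name"]].to_numpy().tolist()
            )
        else:
            name_map = {int(c): f"region{int(c)}" for c in np.unique(labels)}
        out = VertexLabels(labels, name_map)
    else:
        raise ValueError(f"unknown label format {fmt!r}")
    out.validate_for(mesh)
    return out
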