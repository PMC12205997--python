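"""Triangle-mesh container and validity audit.

A :class:`TriangleMesh` is the geometric currency of the whole pipeline:
original cortical surfaces, coarse-grained isosurfaces, convex hulls and
exposed surfaces are all instances.  Vertices are millimetre coordinates in
whatever frame the source file used; every metric downstream is
frame-invariant, so no affine handling is done here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MeshValidationError(ValueError):
    """Raised when a mesh violates a structural invariant."""


@dataclass
class TriangleMesh:
    """Indexed triangle mesh.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        0-based vertex index triples.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    # ------------------------------------------------------------------
    def validate(self, closed: bool = False) -> None:
        """Check structural invariants; raise :class:`MeshValidationError`.

        With ``closed=True`` additionally require that every edge is shared
        by exactly two faces with opposite traversal direction (consistent
        orientation) and that the signed volume is positive (outward
        normals).
        """
        if self.n_vertices == 0:
            raise MeshValidationError("mesh has no vertices")
        f = self.faces
        if f.size and (f.min() < 0 or f.max() >= self.n_vertices):
            raise MeshValidationError("face index out of range")
        if f.size and (
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        ).any():
            raise MeshValidationError("face repeats a vertex index")
        if closed:
            if not self.is_closed():
                raise MeshValidationError("mesh is not closed / consistently oriented")
            if self.signed_volume() <= 0:
                raise MeshValidationError("mesh is not outward-oriented")

    def is_closed(self) -> bool:
        """True if every directed edge has exactly one opposite partner."""
        if self.n_faces == 0:
            return False
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        # A closed, consistently oriented 2-manifold has every directed edge
        # appearing exactly once, and its reverse exactly once.
        order = np.lexsort((e[:, 1], e[:, 0]))
        es = e[order]
        if len(es) != len(np.unique(es, axis=0)):
            return False
        rev = e[:, ::-1]
        e_set = {tuple(x) for x in e}
        return all(tuple(x) in e_set for x in rev)

    def signed_volume(self) -> float:
        """Signed volume via the divergence theorem (positive = outward)."""
        v = self.vertices
        t = v[self.faces]
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def area(self) -> float:
        t = self.vertices[self.faces]
        return float(
            0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1).sum()
        )

    def face_areas(self) -> np.ndarray:
        t = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def flipped(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces[:, ::-1].copy())


@dataclass
class VertexLabels:
    """Per-vertex integer region codes plus a code -> name map."""

    labels: np.ndarray
    name_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
        missing = set(np.unique(self.labels).tolist()) - set(self.name_map)
        if missing:
            raise MeshValidationError(f"label codes without a name_map entry: {sorted(missing)}")

    def validate_for(self, mesh: TriangleMesh) -> None:
        if len(self.labels) != mesh.n_vertices:
            raise MeshValidationError(
                f"label count {len(self.labels)} != vertex count {mesh.n_vertices}"
            )


@dataclass
class CorticalSurfacePair:
    """Pial + white surface for one hemisphere, with optional pial labels."""

    pial: TriangleMesh
    white: TriangleMesh
    labels: VertexLabels | None = None
    hemisphere_id: str = "lh"

    def validate(self) -> None:
        self.pial.validate(closed=True)
        self.white.validate(closed=True)
        if self.labels is not None:
            self.labels.validate_for(self.pial)
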