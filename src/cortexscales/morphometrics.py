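"""Scale-specific morphometrics at hemisphere and lobe level.

Hemisphere metrics at scale lambda: total pial area ``A_t`` (triangle-area
sum of the coarse-grained pial surface), exposed area ``A_e`` (convex-hull
area by default), gray-matter volume ``V_GM`` (GM voxel count times
lambda^3) and average thickness ``T = V_GM / A_t``.  Lobe metrics use
nearest-vertex label transfer from the original surface, majority-vote
triangle assignment for areas, mean minimum pial-vertex-to-white-surface
distance for thickness, and proportional redistribution of the insula into
the frontal, parietal and temporal lobes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .coarse_grain import (
    ScaleLadder,
    VoxelSegmentation,
    close_mask,
    convex_hull_surface,
    extract_isosurface,
    voxelize_pair,
)
from .mesh import CorticalSurfacePair, MeshValidationError, TriangleMesh, VertexLabels

RECIPIENTS = ("frontal", "parietal", "temporal")
LOBES = ("frontal", "parietal", "temporal", "occipital")
NATIVE = "native"


def mesh_area(mesh: TriangleMesh) -> float:
    """Total surface area: sum of triangle areas (mm^2)."""
    return mesh.area()


def mesh_volume(mesh: TriangleMesh) -> float:
    """Signed volume by the divergence theorem (mm^3; positive = outward)."""
    if not mesh.is_closed():
        raise MeshValidationError("volume requires a closed mesh")
    return mesh.signed_volume()


@dataclass
class HemisphereMetrics:
    lam: float | str
    A_t: float
    A_e: float
    T: float
    V_GM: float


def hemisphere_metrics(
    seg: VoxelSegmentation, pial_cg: TriangleMesh, hull: TriangleMesh
) -> HemisphereMetrics:
    """Hemisphere-level metrics from one coarse-graining stage."""
    A_t = mesh_area(pial_cg)
    if A_t <= 0:
        raise MeshValidationError("zero coarse-grained pial area")
    V_GM = seg.gm_volume()
    return HemisphereMetrics(lam=seg.lam, A_t=A_t, A_e=mesh_area(hull), T=V_GM / A_t, V_GM=V_GM)


# ----------------------------------------------------------------------
# label transfer and lobe metrics
# ----------------------------------------------------------------------

def transfer_labels(
    coarse: TriangleMesh, original: TriangleMesh, labels: VertexLabels
) -> VertexLabels:
    """Label each coarse vertex with the Euclidean-nearest original vertex's label."""
    if original.n_vertices == 0:
        raise MeshValidationError("empty original mesh")
    labels.validate_for(original)
    _, idx = cKDTree(original.vertices).query(coarse.vertices)
    return VertexLabels(labels.labels[idx], dict(labels.name_map))


def lobe_areas(mesh: TriangleMesh, labels: VertexLabels) -> dict[str, float]:
    """Per-region area by majority-vote triangle assignment.

    Each triangle goes to the label held by at least 2 of its 3 vertices; a
    3-way tie goes to the lowest region code.  Region areas therefore
    partition the total mesh area exactly.
    """
    labels.validate_for(mesh)
    fl = labels.labels[mesh.faces]  # (m, 3) codes
    lo = fl.min(axis=1)
    hi = fl.max(axis=1)
    mid = fl.sum(axis=1) - lo - hi
    assigned = np.where(mid == hi, hi, lo)  # 2-of-3 majority, ties -> lowest code
    areas = mesh.face_areas()
    out = {name: 0.0 for name in labels.name_map.values()}
    for code, name in labels.name_map.items():
        out[name] = float(areas[assigned == code].sum())
    return out


def _point_triangle_distances(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distance from points[i] to triangle tri[i] (paired, vectorized).

    Closest point is the in-plane projection when its barycentric
    coordinates are non-negative, else the nearest point on one of the
    three edges.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    d20 = np.einsum("ij,ij->i", ap, ab)
    d21 = np.einsum("ij,ij->i", ap, ac)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    inside = (v >= 0) & (w >= 0) & (v + w <= 1)
    proj = a + v[:, None] * ab + w[:, None] * ac
    d_plane = np.linalg.norm(points - proj, axis=1)

    def seg_dist(p, s0, s1):
        d = s1 - s0
        t = np.einsum("ij,ij->i", p - s0, d) / np.maximum(
            np.einsum("ij,ij->i", d, d), 1e-300
        )
        t = np.clip(t, 0.0, 1.0)
        return np.linalg.norm(p - (s0 + t[:, None] * d), axis=1)

    d_edge = np.minimum.reduce(
        [seg_dist(points, a, b), seg_dist(points, b, c), seg_dist(points, c, a)]
    )
    return np.where(inside, d_plane, d_edge)


def min_distances_to_surface(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    """Minimum point-to-triangle distance from each point to the mesh.

    Candidate triangles are pruned with a KD-tree: the nearest-vertex
    distance is an upper bound on the true distance, so only triangles
    whose centroid lies within that bound plus the largest
    centroid-to-vertex radius can be closer.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.vertices[mesh.faces]
    centroids = tri.mean(axis=1)
    r_tri = np.linalg.norm(tri - centroids[:, None, :], axis=2).max()
    d_upper, _ = cKDTree(mesh.vertices).query(points)
    ctree = cKDTree(centroids)
    out = d_upper.copy()  # nearest-vertex distance is attainable
    chunk = 8192  # keep the candidate-pair working set bounded
    for s in range(0, len(points), chunk):
        pts = points[s : s + chunk]
        radius = d_upper[s : s + chunk] + r_tri + 1e-9
        cand = ctree.query_ball_point(pts, radius)
        pi = np.concatenate(
            [np.full(len(c), i, dtype=np.int64) for i, c in enumerate(cand)]
        )
        ti = np.concatenate([np.asarray(c, dtype=np.int64) for c in cand])
        for ps in range(0, len(ti), 2_000_000):
            sl = slice(ps, ps + 2_000_000)
            d = _point_triangle_distances(pts[pi[sl]], tri[ti[sl]])
            np.minimum.at(out[s : s + chunk], pi[sl], d)
    return out


def lobe_thickness(
    pial: TriangleMesh, white: TriangleMesh, labels: VertexLabels
) -> dict[str, float | None]:
    """Per-region mean minimum distance from pial vertices to the white surface.

    Empty regions yield ``None`` (absent, not zero).
    """
    labels.validate_for(pial)
    if white.n_faces == 0:
        raise MeshValidationError("white mesh has no faces")
    d = min_distances_to_surface(pial.vertices, white)
    out: dict[str, float | None] = {}
    for code, name in labels.name_map.items():
        sel = labels.labels == code
        out[name] = float(d[sel].mean()) if sel.any() else None
    return out


def vertex_counts(labels: VertexLabels) -> dict[str, int]:
    return {
        name: int((labels.labels == code).sum()) for code, name in labels.name_map.items()
    }


@dataclass
class LobeMetrics:
    lam: float | str
    A_t: dict[str, float]
    T: dict[str, float]
    A_e: dict[str, float] | None = None


def redistribute_insula(
    areas: dict[str, float],
    thickness: dict[str, float | None],
    exposed: dict[str, float] | None = None,
    lam: float | str = NATIVE,
) -> LobeMetrics:
    """Fold the insula into frontal/parietal/temporal by relative area.

    Area: each recipient lobe gains ``A_ins * A_lobe / sum(recipient A)``;
    the occipital lobe is untouched, so total area is conserved exactly.
    Thickness: recipient values are replaced by the area-weighted mean of
    the lobe's own T and the transferred insular share, which conserves the
    area-weighted mean thickness of the five-region set.
    """
    a_ins = areas.get("insula", 0.0)
    rec_total = sum(areas[r] for r in RECIPIENTS)
    if a_ins > 0 and rec_total <= 0:
        raise MeshValidationError("insula present but all recipient lobes have zero area")
    out_a: dict[str, float] = {}
    out_t: dict[str, float] = {}
    t_ins = thickness.get("insula")
    for lobe in LOBES:
        a = areas[lobe]
        t = thickness.get(lobe)
        if lobe in RECIPIENTS and a_ins > 0:
            share = a_ins * a / rec_total
            if t is not None and t_ins is not None and (a + share) > 0:
                t = (a * t + share * t_ins) / (a + share)
            a = a + share
        out_a[lobe] = a
        out_t[lobe] = t
    out_e = None
    if exposed is not None:
        e_ins = exposed.get("insula", 0.0)
        e_rec = sum(exposed[r] for r in RECIPIENTS)
        out_e = {}
        for lobe in LOBES:
            e = exposed[lobe]
            if lobe in RECIPIENTS and e_ins > 0 and e_rec > 0:
                e = e + e_ins * e / e_rec
            out_e[lobe] = e
    return LobeMetrics(lam=lam, A_t=out_a, T=out_t, A_e=out_e)


# ----------------------------------------------------------------------
# scale sweep
# ----------------------------------------------------------------------

@dataclass
class SweepConfig:
    """Configuration of one multiscale sweep."""

    closing_diameter: float = 15.0  # mm, ball for the closing operation
    ae_mode: str = "hull"  # hemisphere exposed surface: "hull" or "closing"
    smooth_sigma: float = 0.8  # isosurface anti-aliasing, voxels
    lobe_metrics: bool = True  # only applies when the pair carries labels
    lobe_exposed: bool = False  # closing-based lobal A_e (slow at small lambda)
    subject_id: str = "synthetic"
    fixed_origin: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


_COLUMNS = ["subject_id", "hemisphere", "structure", "lambda", "metric", "value"]


def _rows(subject, hemi, structure, lam, metrics: dict[str, float | None]):
    lam_val = lam if isinstance(lam, str) else repr(float(lam))
    return [
        {
            "subject_id": subject,
            "hemisphere": hemi,
            "structure": structure,
            "lambda": lam_val,
            "metric": m,
            "value": v,
        }
        for m, v in metrics.items()
        if v is not None
    ]


def _native_rows(pair: CorticalSurfacePair, config: SweepConfig) -> list[dict]:
    A_t = mesh_area(pair.pial)
    V_GM = mesh_volume(pair.pial) - mesh_volume(pair.white)
    hull = convex_hull_surface(pair.pial)
    rows = _rows(
        config.subject_id,
        pair.hemisphere_id,
        "hemisphere",
        NATIVE,
        {"A_t": A_t, "A_e": mesh_area(hull), "T": V_GM / A_t, "V_GM": V_GM},
    )
    if config.lobe_metrics and pair.labels is not None:
        lm = redistribute_insula(
            lobe_areas(pair.pial, pair.labels),
            lobe_thickness(pair.pial, pair.white, pair.labels),
            lam=NATIVE,
        )
        for lobe in LOBES:
            rows += _rows(
                config.subject_id,
                pair.hemisphere_id,
                lobe,
                NATIVE,
                {"A_t": lm.A_t[lobe], "T": lm.T[lobe]},
            )
    return rows


def sweep_single_scale(
    pair: CorticalSurfacePair, lam: float, config: SweepConfig
) -> list[dict]:
    """Run voxelize -> isosurface -> hull/closing -> metrics at one scale."""
    seg = voxelize_pair(pair, lam, origin=config.fixed_origin)
    pial_cg = extract_isosurface(seg, "pial", smooth_sigma=config.smooth_sigma)
    white_cg = extract_isosurface(seg, "white", smooth_sigma=config.smooth_sigma)
    hull = convex_hull_surface(pial_cg)
    closed_surface = None
    if config.ae_mode == "closing" or (config.lobe_metrics and config.lobe_exposed):
        closed_seg = close_mask(seg, config.closing_diameter)
        closed_surface = extract_isosurface(
            closed_seg, "pial", smooth_sigma=config.smooth_sigma
        )
    hm = hemisphere_metrics(seg, pial_cg, hull)
    if config.ae_mode == "closing":
        hm.A_e = mesh_area(closed_surface)
    rows = _rows(
        config.subject_id,
        pair.hemisphere_id,
        "hemisphere",
        lam,
        {"A_t": hm.A_t, "A_e": hm.A_e, "T": hm.T, "V_GM": hm.V_GM},
    )
    if config.lobe_metrics and pair.labels is not None:
        cg_labels = transfer_labels(pial_cg, pair.pial, pair.labels)
        exposed = None
        if config.lobe_exposed and closed_surface is not None:
            exp_labels = transfer_labels(closed_surface, pair.pial, pair.labels)
            exposed = lobe_areas(closed_surface, exp_labels)
        lm = redistribute_insula(
            lobe_areas(pial_cg, cg_labels),
            lobe_thickness(pial_cg, white_cg, cg_labels),
            exposed=exposed,
            lam=lam,
        )
        for lobe in LOBES:
            metrics = {"A_t": lm.A_t[lobe], "T": lm.T[lobe]}
            if lm.A_e is not None:
                metrics["A_e"] = lm.A_e[lobe]
            rows += _rows(config.subject_id, pair.hemisphere_id, lobe, lam, metrics)
    return rows


def run_scale_sweep(
    pair: CorticalSurfacePair,
    ladder: ScaleLadder,
    config: SweepConfig | None = None,
) -> pd.DataFrame:
    """Full multiscale sweep: every ladder scale plus one native entry.

    Returns a tidy table (subject_id, hemisphere, structure, lambda,
    metric, value); ``lambda`` holds full-precision decimal strings, or the
    sentinel ``"native"`` for the uncoarsened surfaces.
    """
    if config is None:
        config = SweepConfig()
    if len(ladder) == 0:
        raise ValueError("empty scale ladder")
    pair.validate()
    rows = _native_rows(pair, config)
    for lam in ladder:
        try:
            rows += sweep_single_scale(pair, float(lam), config)
        except Exception as exc:
            raise RuntimeError(f"scale sweep failed at lambda={lam:.4f} mm") from exc
    return pd.DataFrame(rows, columns=_COLUMNS)


def table_lambdas(table: pd.DataFrame) -> np.ndarray:
    """Distinct numeric lambdas of a multiscale table, ascending."""
    vals = [v for v in table["lambda"].unique() if v != NATIVE]
    return np.sort(np.array([float(v) for v in vals]))


def metric_by_scale(
    table: pd.DataFrame, metric: str, structure: str = "hemisphere"
) -> pd.Series:
    """Series of one metric indexed by lambda (floats; native = NaN index)."""
    sel = table[(table["metric"] == metric) & (table["structure"] == structure)]
    idx = [np.nan if v == NATIVE else float(v) for v in sel["lambda"]]
    return pd.Series(sel["value"].to_numpy(), index=idx).sort_index()
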