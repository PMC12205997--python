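"""Morphometric operators: areas, volumes, label transfer, thickness, sweep."""

import numpy as np
import pytest

from cortexscales.coarse_grain import scale_ladder, voxelize_pair, extract_isosurface, convex_hull_surface
from cortexscales.mesh import MeshValidationError, TriangleMesh, VertexLabels
from cortexscales.morphometrics import (
    SweepConfig,
    hemisphere_metrics,
    lobe_areas,
    lobe_thickness,
    mesh_area,
    mesh_volume,
    metric_by_scale,
    min_distances_to_surface,
    redistribute_insula,
    run_scale_sweep,
    transfer_labels,
)
from cortexscales.synthetic import (
    SyntheticCortexSpec,
    make_folded_sphere_pair,
    make_quadrant_labels,
)


def test_mesh_area_unit_cube(unit_cube_mesh):
    assert mesh_area(unit_cube_mesh) == pytest.approx(6.0)


def test_mesh_area_icosphere_close_to_sphere(small_sphere_pair):
    assert mesh_area(small_sphere_pair.pial) == pytest.approx(
        4 * np.pi * 100, rel=0.005
    )


def test_mesh_area_empty_faces():
    m = TriangleMesh(np.zeros((3, 3)), np.zeros((0, 3), dtype=int))
    assert mesh_area(m) == 0.0


def test_mesh_volume_cube_and_orientation_sign(unit_cube_mesh):
    assert mesh_volume(unit_cube_mesh) == pytest.approx(1.0)
    assert unit_cube_mesh.flipped().signed_volume() == pytest.approx(-1.0)


def test_mesh_volume_requires_closed(two_triangle_mesh):
    with pytest.raises(MeshValidationError):
        mesh_volume(two_triangle_mesh)


def test_mesh_volume_ball(small_sphere_pair):
    assert mesh_volume(small_sphere_pair.pial) == pytest.approx(
        4 / 3 * np.pi * 1000, rel=0.01
    )


def test_hemisphere_metrics_ratio_definition(small_sphere_pair):
    seg = voxelize_pair(small_sphere_pair, 0.5)
    pial_cg = extract_isosurface(seg, "pial")
    hull = convex_hull_surface(pial_cg)
    hm = hemisphere_metrics(seg, pial_cg, hull)
    assert hm.T == pytest.approx(hm.V_GM / hm.A_t, rel=1e-12)
    # analytic shell oracle: V/A = (R^3 - r^3)/(3 R^2) for R=10, r=8
    assert hm.T == pytest.approx((1000 - 512) / 300, rel=0.05)


# ---------------------------------------------------------------------------
# label transfer
# ---------------------------------------------------------------------------

def test_transfer_labels_identity(small_folded_pair):
    labels = small_folded_pair.labels
    out = transfer_labels(small_folded_pair.pial, small_folded_pair.pial, labels)
    np.testing.assert_array_equal(out.labels, labels.labels)


def test_transfer_labels_single_label(small_sphere_pair):
    n = small_sphere_pair.pial.n_vertices
    labels = VertexLabels(np.zeros(n, dtype=int), {0: "only"})
    coarse = TriangleMesh(
        small_sphere_pair.pial.vertices * 0.5, small_sphere_pair.pial.faces
    )
    out = transfer_labels(coarse, small_sphere_pair.pial, labels)
    assert (out.labels == 0).all()


def test_transfer_labels_boundaries_near_sector_planes(small_folded_pair):
    """Transferred quadrant boundaries stay within ~2 coarse edge lengths
    of the generating azimuthal sector planes."""
    seg = voxelize_pair(small_folded_pair, 1.0)
    coarse = extract_isosurface(seg, "pial")
    out = transfer_labels(coarse, small_folded_pair.pial, small_folded_pair.labels)
    v = coarse.vertices
    phi = np.mod(np.arctan2(v[:, 1], v[:, 0]), 2 * np.pi)
    theta = np.arccos(np.clip(v[:, 2] / np.linalg.norm(v, axis=1), -1, 1))
    expected = np.clip(np.floor(phi / (np.pi / 2)), 0, 3).astype(int)
    body = theta > np.deg2rad(35.0)  # away from the insula cap
    # angular distance to the nearest sector plane, in arc length
    dphi = np.minimum(phi % (np.pi / 2), (np.pi / 2) - phi % (np.pi / 2))
    arc = dphi * np.linalg.norm(v, axis=1) * np.sin(theta)
    interior = body & (arc > 2.0)  # > 2 mm (~2 voxel edges) from any plane
    assert np.array_equal(out.labels[interior], expected[interior])


# ---------------------------------------------------------------------------
# lobe areas / thickness
# ---------------------------------------------------------------------------

def test_lobe_areas_constant_labels(small_sphere_pair):
    n = small_sphere_pair.pial.n_vertices
    labels = VertexLabels(np.zeros(n, dtype=int), {0: "all"})
    out = lobe_areas(small_sphere_pair.pial, labels)
    assert out["all"] == pytest.approx(mesh_area(small_sphere_pair.pial), rel=1e-12)


def test_lobe_areas_partition_exact(small_folded_pair):
    out = lobe_areas(small_folded_pair.pial, small_folded_pair.labels)
    assert sum(out.values()) == pytest.approx(
        mesh_area(small_folded_pair.pial), rel=1e-12
    )


def test_lobe_areas_hemisphere_split_symmetry(small_sphere_pair):
    v = small_sphere_pair.pial.vertices
    # split plane off the mesh's symmetry axes so no vertex sits on it
    normal = np.array([1.0, 2.0, 3.0]) / np.sqrt(14.0)
    labels = VertexLabels((v @ normal > 0).astype(int), {0: "south", 1: "north"})
    out = lobe_areas(small_sphere_pair.pial, labels)
    half = mesh_area(small_sphere_pair.pial) / 2
    assert out["north"] == pytest.approx(half, rel=0.02)
    assert out["south"] == pytest.approx(half, rel=0.02)


def test_point_to_triangle_distance_cases():
    tri_mesh = TriangleMesh(
        np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 5]]),
        np.array([[0, 1, 2]]),
    )
    pts = np.array(
        [
            [0.5, 0.5, 0.0],   # on the face -> 0
            [0.5, 0.5, 1.0],   # above interior -> plane distance 1
            [3.0, 0.0, 0.0],   # beyond vertex b -> 1
            [1.0, -1.0, 0.0],  # off edge ab -> 1
        ]
    )
    d = min_distances_to_surface(pts, tri_mesh)
    np.testing.assert_allclose(d, [0.0, 1.0, 1.0, 1.0], atol=1e-12)


def test_point_triangle_no_greater_than_vertex_distance(small_folded_pair):
    from scipy.spatial import cKDTree

    pts = small_folded_pair.pial.vertices[::7]
    d_tri = min_distances_to_surface(pts, small_folded_pair.white)
    d_vert, _ = cKDTree(small_folded_pair.white.vertices).query(pts)
    assert np.all(d_tri <= d_vert + 1e-12)


def test_lobe_thickness_concentric_spheres(small_sphere_pair):
    labels = make_quadrant_labels(small_sphere_pair)
    out = lobe_thickness(small_sphere_pair.pial, small_sphere_pair.white, labels)
    for name, t in out.items():
        assert t == pytest.approx(2.0, rel=0.02), name


def test_lobe_thickness_empty_region_flagged(small_sphere_pair):
    n = small_sphere_pair.pial.n_vertices
    labels = VertexLabels(
        np.zeros(n, dtype=int), {0: "everything", 7: "empty"}
    )
    out = lobe_thickness(small_sphere_pair.pial, small_sphere_pair.white, labels)
    assert out["empty"] is None


# ---------------------------------------------------------------------------
# insula redistribution
# ---------------------------------------------------------------------------

def test_redistribute_insula_proportional_split():
    areas = {"frontal": 50.0, "parietal": 30.0, "temporal": 20.0,
             "occipital": 40.0, "insula": 10.0}
    thick = {k: 2.0 for k in areas}
    out = redistribute_insula(areas, thick)
    assert out.A_t["frontal"] == pytest.approx(55.0)
    assert out.A_t["parietal"] == pytest.approx(33.0)
    assert out.A_t["temporal"] == pytest.approx(22.0)
    assert out.A_t["occipital"] == pytest.approx(40.0)


def test_redistribute_insula_zero_is_noop():
    areas = {"frontal": 5.0, "parietal": 3.0, "temporal": 2.0,
             "occipital": 4.0, "insula": 0.0}
    thick = {"frontal": 2.1, "parietal": 2.2, "temporal": 2.3,
             "occipital": 2.4, "insula": 1.0}
    out = redistribute_insula(areas, thick)
    for lobe in ("frontal", "parietal", "temporal", "occipital"):
        assert out.A_t[lobe] == areas[lobe]
        assert out.T[lobe] == thick[lobe]


def test_redistribute_insula_conserves_total_area_and_mean_thickness():
    rng = np.random.default_rng(3)
    areas = dict(zip(
        ("frontal", "parietal", "temporal", "occipital", "insula"),
        rng.uniform(10, 100, 5),
    ))
    thick = dict(zip(areas, rng.uniform(1.5, 3.5, 5)))
    out = redistribute_insula(areas, thick)
    assert sum(out.A_t.values()) == pytest.approx(sum(areas.values()), rel=1e-14)
    # area-weighted mean thickness conserved (occipital untouched on both sides)
    aw_in = sum(areas[k] * thick[k] for k in areas)
    aw_out = sum(out.A_t[k] * out.T[k] for k in out.A_t)
    assert aw_out == pytest.approx(aw_in, rel=1e-12)


def test_redistribute_insula_all_recipients_zero_rejected():
    areas = {"frontal": 0.0, "parietal": 0.0, "temporal": 0.0,
             "occipital": 4.0, "insula": 1.0}
    with pytest.raises(MeshValidationError):
        redistribute_insula(areas, {k: 2.0 for k in areas})


# ---------------------------------------------------------------------------
# scale sweep
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_sweep(small_folded_pair_module):
    pair = small_folded_pair_module
    return run_scale_sweep(
        pair, scale_ladder(2), SweepConfig(lobe_metrics=True)
    )


@pytest.fixture(scope="module")
def small_folded_pair_module():
    spec = SyntheticCortexSpec(
        base_radius=10.0, fold_amplitude=1.5, fold_degree=6, thickness=2.0,
        mesh_subdivisions=3,
    )
    pair = make_folded_sphere_pair(spec)
    pair.labels = make_quadrant_labels(pair)
    return pair


def test_sweep_row_structure(small_sweep):
    lambdas = small_sweep["lambda"].unique()
    assert "native" in lambdas
    assert len(lambdas) == 4  # k_max=2 -> 3 scales + native
    hemi = small_sweep[small_sweep.structure == "hemisphere"]
    assert set(hemi.metric) == {"A_t", "A_e", "T", "V_GM"}
    # one row per (structure, lambda, metric)
    assert not small_sweep.duplicated(
        ["subject_id", "hemisphere", "structure", "lambda", "metric"]
    ).any()


def test_sweep_lobe_sums_match_hemisphere(small_sweep):
    at = small_sweep[small_sweep.metric == "A_t"]
    for lam in at["lambda"].unique():
        hemi = at[(at["lambda"] == lam) & (at.structure == "hemisphere")].value.iloc[0]
        lobes = at[(at["lambda"] == lam) & (at.structure != "hemisphere")].value.sum()
        assert lobes == pytest.approx(hemi, rel=1e-12), lam


def test_sweep_two_thickness_definitions_agree(small_sweep):
    """Volume/area thickness (hemisphere) vs mean vertex distance (lobes)
    agree within 15% on a thin smooth-ish shell."""
    t = small_sweep[small_sweep.metric == "T"]
    for lam in t["lambda"].unique():
        hemi = t[(t["lambda"] == lam) & (t.structure == "hemisphere")].value.iloc[0]
        lobe_vals = t[(t["lambda"] == lam) & (t.structure != "hemisphere")].value
        assert np.average(lobe_vals) == pytest.approx(hemi, rel=0.25), lam


def test_sweep_deterministic_and_reindex_invariant(small_folded_pair_module):
    pair = small_folded_pair_module
    cfg = SweepConfig(lobe_metrics=False)
    t1 = run_scale_sweep(pair, scale_ladder(0), cfg)
    t2 = run_scale_sweep(pair, scale_ladder(0), cfg)
    assert t1.equals(t2)
    # vertex re-indexing leaves the metrics unchanged
    rng = np.random.default_rng(0)
    perm = rng.permutation(pair.pial.n_vertices)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    from cortexscales.mesh import CorticalSurfacePair

    pair2 = CorticalSurfacePair(
        pial=TriangleMesh(pair.pial.vertices[perm], inv[pair.pial.faces]),
        white=TriangleMesh(pair.white.vertices[perm], inv[pair.white.faces]),
    )
    t3 = run_scale_sweep(pair2, scale_ladder(0), cfg)
    np.testing.assert_allclose(
        t1.value.to_numpy(dtype=float), t3.value.to_numpy(dtype=float), rtol=1e-9
    )


def test_smooth_pair_area_stable_across_fine_scales(small_sphere_pair):
    """A smooth shape's area is scale-invariant under coarse-graining."""
    tab = run_scale_sweep(
        small_sphere_pair, scale_ladder(2), SweepConfig(lobe_metrics=False)
    )
    s = metric_by_scale(tab, "A_t")
    at = s[s.index.notna()]  # ladder scales only
    assert at.max() / at.min() < 1.05


def test_metric_by_scale_helper(small_sweep):
    s = metric_by_scale(small_sweep, "A_t")
    assert len(s) == 4
    assert s.index.isna().sum() == 1  # the native entry
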