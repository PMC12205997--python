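"""Coarse-graining core: ladder, voxelization, isosurfacing, closing, hull."""

import numpy as np
import pytest

from cortexscales.coarse_grain import (
    BG,
    GM,
    WM,
    DegenerateGridError,
    VoxelSegmentation,
    close_mask,
    convex_hull_surface,
    extract_isosurface,
    scale_ladder,
    voxelize_pair,
)
from cortexscales.mesh import CorticalSurfacePair, MeshValidationError, TriangleMesh
from cortexscales.morphometrics import mesh_area, mesh_volume
from cortexscales.synthetic import SyntheticCortexSpec, make_folded_sphere_pair
from cortexscales._inside import points_in_mesh, winding_number


# ---------------------------------------------------------------------------
# scale ladder
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "k, display",
    [(0, "0.32"), (1, "0.37"), (11, "1.86"), (14, "3.02")],
)
def test_ladder_values_round_to_conventional_labels(k, display):
    lad = scale_ladder(14)
    assert f"{lad.scales[k]:.2f}" == display
    assert np.isclose(lad.scales[k], 10 ** (-0.5 + 0.07 * k))


def test_ladder_strictly_increasing_and_sized():
    lad = scale_ladder(14)
    assert len(lad) == 15
    assert np.all(np.diff(lad.scales) > 0)
    with pytest.raises(ValueError):
        scale_ladder(-1)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def test_voxelized_shell_volume_matches_divergence_oracle(small_sphere_pair):
    seg = voxelize_pair(small_sphere_pair, 0.5)
    truth = mesh_volume(small_sphere_pair.pial) - mesh_volume(small_sphere_pair.white)
    assert seg.gm_volume() == pytest.approx(truth, rel=0.05)


def test_identical_meshes_give_zero_gm(small_sphere_pair):
    pair = CorticalSurfacePair(
        pial=small_sphere_pair.pial, white=small_sphere_pair.pial
    )
    seg = voxelize_pair(pair, 1.0)
    assert seg.counts()["GM"] == 0
    assert seg.counts()["WM"] > 0


def test_padding_margin_invariant(small_folded_pair):
    seg = voxelize_pair(small_folded_pair, 1.0)
    seg.validate()  # raises if any non-BG voxel touches the grid boundary


def test_degenerate_scale_rejected(small_sphere_pair):
    with pytest.raises(DegenerateGridError):
        voxelize_pair(small_sphere_pair, 50.0)


def test_voxel_labels_match_winding_oracle(small_folded_pair):
    """Every voxel label agrees with an independent winding-number test."""
    seg = voxelize_pair(small_folded_pair, 1.2)
    idx = np.argwhere(np.ones(seg.grid.shape, dtype=bool))
    centers = seg.origin + (idx + 0.5) * seg.lam
    in_pial = points_in_mesh(centers, small_folded_pair.pial).reshape(seg.grid.shape)
    in_white = points_in_mesh(centers, small_folded_pair.white).reshape(seg.grid.shape)
    expected = np.where(in_white, WM, np.where(in_pial, GM, BG)).astype(np.uint8)
    np.testing.assert_array_equal(seg.grid, expected)


def test_voxel_labels_match_analytic_sphere_oracle(small_sphere_pair):
    """For concentric spheres the label of almost every voxel center is
    predicted by its radius alone; only centers within one chord-sagitta of
    the faceted surface may differ from the smooth ideal."""
    seg = voxelize_pair(small_sphere_pair, 1.5)
    idx = np.argwhere(np.ones(seg.grid.shape, dtype=bool))
    centers = seg.origin + (idx + 0.5) * seg.lam
    r = np.linalg.norm(centers, axis=1).reshape(seg.grid.shape)
    # mesh faceting keeps the polyhedral surface within this band of the sphere
    sagitta = 0.15
    expected_wm = r < 8.0 - sagitta
    expected_bg = r > 10.0 + sagitta
    assert np.all(seg.grid[expected_wm] == WM)
    assert np.all(seg.grid[expected_bg] == BG)
    band = (r > 8.0 + sagitta) & (r < 10.0 - sagitta)
    assert np.all(seg.grid[band] == GM)


def test_translation_by_lambda_multiples_is_invariant(small_folded_pair):
    lam = 1.0
    seg0 = voxelize_pair(small_folded_pair, lam)
    shifted = CorticalSurfacePair(
        pial=TriangleMesh(
            small_folded_pair.pial.vertices + np.array([3.0, -2.0, 5.0]) * lam,
            small_folded_pair.pial.faces,
        ),
        white=TriangleMesh(
            small_folded_pair.white.vertices + np.array([3.0, -2.0, 5.0]) * lam,
            small_folded_pair.white.faces,
        ),
    )
    seg1 = voxelize_pair(shifted, lam)
    np.testing.assert_array_equal(seg0.grid, seg1.grid)


# ---------------------------------------------------------------------------
# isosurface
# ---------------------------------------------------------------------------

def _single_voxel_seg(lam=1.0):
    grid = np.zeros((3, 3, 3), dtype=np.uint8)
    grid[1, 1, 1] = GM
    return VoxelSegmentation(origin=np.zeros(3), lam=lam, grid=grid)


def test_single_voxel_binary_isosurface_is_octahedron():
    seg = _single_voxel_seg()
    mesh = extract_isosurface(seg, "pial", smooth_sigma=0.0)
    # midpoint interpolation at level 0.5 forces the regular octahedron
    assert mesh.area() == pytest.approx(np.sqrt(3.0), rel=1e-6)
    assert mesh.n_faces == 8


def test_solid_cube_isosurface_area_converges():
    n = 20
    grid = np.zeros((n + 2,) * 3, dtype=np.uint8)
    grid[1:-1, 1:-1, 1:-1] = GM
    seg = VoxelSegmentation(origin=np.zeros(3), lam=1.0, grid=grid)
    mesh = extract_isosurface(seg, "pial", smooth_sigma=0.0)
    assert mesh.area() == pytest.approx(6 * n**2, rel=0.05)


def test_isosurface_closed_and_outward(small_folded_pair):
    seg = voxelize_pair(small_folded_pair, 1.0)
    for tissue in ("pial", "white"):
        mesh = extract_isosurface(seg, tissue)
        assert mesh.is_closed()
        assert mesh.signed_volume() > 0


def test_isosurface_empty_tissue_rejected():
    seg = _single_voxel_seg()
    with pytest.raises(MeshValidationError):
        extract_isosurface(seg, "white")


def test_smooth_sphere_area_refinement():
    """Coarse-grained area converges to the analytic sphere area as the
    scale shrinks (within 3% at lambda = R/60)."""
    spec = SyntheticCortexSpec(base_radius=30.0, thickness=2.5, mesh_subdivisions=4)
    pair = make_folded_sphere_pair(spec)
    seg = voxelize_pair(pair, 0.5)
    mesh = extract_isosurface(seg, "pial")
    assert mesh.area() == pytest.approx(4 * np.pi * 30**2, rel=0.03)


# ---------------------------------------------------------------------------
# closing
# ---------------------------------------------------------------------------

def _ball_seg(r_vox=6, lam=1.0):
    n = 2 * r_vox + 5
    idx = np.indices((n, n, n)).transpose(1, 2, 3, 0)
    center = (n - 1) / 2
    ball = ((idx - center) ** 2).sum(axis=-1) <= r_vox**2
    grid = np.where(ball, GM, BG).astype(np.uint8)
    return VoxelSegmentation(origin=np.zeros(3), lam=lam, grid=grid)


def test_closing_is_identity_on_convex_ball():
    seg = _ball_seg()
    closed = close_mask(seg, diameter=6.0)
    a0, a1 = seg.grid != BG, closed.grid != BG
    # compare on the common (original) region of the expanded grid
    r = (closed.grid.shape[0] - seg.grid.shape[0]) // 2
    inner = closed.grid[r:-r, r:-r, r:-r] != BG
    np.testing.assert_array_equal(inner, a0)


def test_closing_with_subvoxel_diameter_is_identity():
    seg = _ball_seg()
    closed = close_mask(seg, diameter=0.5)
    np.testing.assert_array_equal(closed.grid, seg.grid)
    np.testing.assert_array_equal(closed.origin, seg.origin)


def test_closing_bridges_parallel_slabs():
    """Two 5 mm-separated slabs: a 15 mm ball closing fills the gap."""
    grid = np.zeros((30, 30, 16), dtype=np.uint8)
    grid[5:25, 5:25, 3:6] = GM
    grid[5:25, 5:25, 11:14] = GM  # 5 voxels (=5 mm) gap
    seg = VoxelSegmentation(origin=np.zeros(3), lam=1.0, grid=grid)
    closed = close_mask(seg, diameter=15.0)
    p = (closed.grid.shape[2] - 16) // 2
    gap = closed.grid[15 + p, 15 + p, 6 + p : 11 + p]
    assert (gap != BG).all()


def test_closing_result_superset_of_input(small_folded_pair):
    seg = voxelize_pair(small_folded_pair, 1.0)
    closed = close_mask(seg, diameter=15.0)
    r = int(round((seg.origin - closed.origin)[0] / seg.lam))
    sl = tuple(slice(r, r + s) for s in seg.grid.shape)
    assert np.all((closed.grid[sl] != BG) | (seg.grid == BG))


def test_closing_agrees_with_scipy_structuring_element():
    """EDT-based closing equals scipy's binary_closing with the same ball."""
    from scipy import ndimage

    rng = np.random.default_rng(0)
    grid = np.zeros((18, 18, 18), dtype=np.uint8)
    blob = rng.random((10, 10, 10)) > 0.6
    grid[4:14, 4:14, 4:14] = np.where(blob, GM, BG)
    seg = VoxelSegmentation(origin=np.zeros(3), lam=1.0, grid=grid)
    r = 2
    closed = close_mask(seg, diameter=2 * r)
    idx = np.indices((2 * r + 1,) * 3) - r
    ball = (idx**2).sum(axis=0) <= r**2
    p = r + 1
    ref = ndimage.binary_closing(np.pad(seg.grid != BG, p), structure=ball)
    got = closed.grid != BG
    np.testing.assert_array_equal(got, ref)


# ---------------------------------------------------------------------------
# convex hull
# ---------------------------------------------------------------------------

def test_hull_of_cube_corners(unit_cube_mesh):
    mesh = TriangleMesh(unit_cube_mesh.vertices * 2.0, unit_cube_mesh.faces)
    hull = convex_hull_surface(mesh)
    assert hull.area() == pytest.approx(24.0, rel=1e-9)
    assert hull.is_closed()
    assert hull.signed_volume() == pytest.approx(8.0, rel=1e-9)


def test_hull_of_convex_mesh_matches_mesh_area(small_sphere_pair):
    hull = convex_hull_surface(small_sphere_pair.pial)
    assert hull.area() == pytest.approx(small_sphere_pair.pial.area(), rel=0.005)


def test_hull_smaller_than_folded_area(small_folded_pair):
    hull = convex_hull_surface(small_folded_pair.pial)
    assert hull.area() < small_folded_pair.pial.area()


def test_hull_degenerate_input_rejected():
    flat = TriangleMesh(
        np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]),
        np.array([[0, 1, 2]]),
    )
    with pytest.raises(MeshValidationError):
        convex_hull_surface(flat)


def test_feature_removal_regimes():
    """Scales below a tenth of the fold wavelength retain the folded area
    (within 10%); a scale at the fold wavelength removes the folds and
    approaches the smooth envelope's area (within 10%)."""
    # fine regime: w = 2*pi*30/12 = 15.7 mm, lambda = 0.32 = w/49
    spec = SyntheticCortexSpec(
        base_radius=30.0, fold_amplitude=3.0, fold_degree=12, thickness=2.5,
        mesh_subdivisions=4,
    )
    pair = make_folded_sphere_pair(spec)
    folded = mesh_area(pair.pial)
    seg = voxelize_pair(pair, 10 ** -0.5)
    a_fine = extract_isosurface(seg, "pial").area()
    assert a_fine == pytest.approx(folded, rel=0.10)

    # coarse regime: w = 6.28 mm folds, lambda = w
    spec = SyntheticCortexSpec(
        base_radius=30.0, fold_amplitude=1.5, fold_degree=30, thickness=2.5,
        mesh_subdivisions=5,
    )
    pair = make_folded_sphere_pair(spec)
    w = spec.fold_wavelength
    seg = voxelize_pair(pair, w)
    a_coarse = extract_isosurface(seg, "pial").area()
    assert a_coarse == pytest.approx(4 * np.pi * 30**2, rel=0.10)


def test_winding_number_inside_outside_values(unit_cube_mesh):
    pts = np.array([[0.5, 0.5, 0.5], [2.0, 2.0, 2.0]])
    w = winding_number(pts, unit_cube_mesh)
    assert w[0] == pytest.approx(1.0, abs=1e-9)
    assert w[1] == pytest.approx(0.0, abs=1e-9)
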