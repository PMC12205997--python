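import numpy as np
import pytest

from cortexscales.synthetic import (
    SyntheticCortexSpec,
    make_folded_sphere_pair,
    make_quadrant_labels,
)


@pytest.fixture(scope="session")
def small_sphere_pair():
    """Concentric spheres R=10, t=2, coarse mesh — cheap geometric fixture."""
    spec = SyntheticCortexSpec(
        base_radius=10.0, fold_amplitude=0.0, fold_degree=0, thickness=2.0,
        mesh_subdivisions=3,
    )
    return make_folded_sphere_pair(spec)


@pytest.fixture(scope="session")
def small_folded_pair():
    """Folded sphere R=10, a=1.5, m=6 with quadrant labels — cheap."""
    spec = SyntheticCortexSpec(
        base_radius=10.0, fold_amplitude=1.5, fold_degree=6, thickness=2.0,
        mesh_subdivisions=3,
    )
    pair = make_folded_sphere_pair(spec)
    pair.labels = make_quadrant_labels(pair)
    return pair


@pytest.fixture
def two_triangle_mesh():
    from cortexscales.mesh import TriangleMesh

    verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
    faces = np.array([[0, 1, 2], [2, 1, 3]])
    return TriangleMesh(verts, faces)


@pytest.fixture
def unit_cube_mesh():
    """Closed, outward-oriented unit cube (8 vertices, 12 triangles)."""
    from cortexscales.mesh import TriangleMesh

    v = np.array(
        [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
    )
    f = np.array(
        [
            [0, 1, 3], [0, 3, 2],  # x=0 face, normal -x
            [4, 6, 7], [4, 7, 5],  # x=1 face, normal +x
            [0, 4, 5], [0, 5, 1],  # y=0
            [2, 3, 7], [2, 7, 6],  # y=1
            [0, 2, 6], [0, 6, 4],  # z=0
            [1, 5, 7], [1, 7, 3],  # z=1
        ]
    )
    return TriangleMesh(v, f)
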