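import numpy as np
import pytest

from ishnet.mesh import TriangleMesh, assign_pixels_to_triangles, build_standard_mesh


@pytest.fixture(scope="session")
def default_mesh():
    """The default 311-triangle mesh (expensive-ish, shared across tests)."""
    return build_standard_mesh()


@pytest.fixture(scope="session")
def assigned_mesh():
    """Default mesh with pixel assignment for a 200x100 frame."""
    mesh = build_standard_mesh()
    return assign_pixels_to_triangles(mesh, width=200, height=100)


@pytest.fixture(scope="session")
def small_mesh():
    """A coarse ~40-triangle mesh with a 64x32 assignment, for fast tests."""
    mesh = build_standard_mesh(target_triangle_count=40)
    return assign_pixels_to_triangles(mesh, width=64, height=32)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def one_triangle_mesh(width, height):
    """A single huge triangle covering the whole raster frame."""
    verts = np.array([[-50.0, -50.0], [50.0, -50.0], [0.0, 50.0]])
    mesh = TriangleMesh(vertices=verts, triangles=np.array([[0, 1, 2]]))
    return assign_pixels_to_triangles(mesh, width=width, height=height)
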