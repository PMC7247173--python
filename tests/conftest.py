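import numpy as np
import pytest

from molcsg.fixtures import toy_molecule
from molcsg.mesher import mesh_solid_boundary
from molcsg.molecular import build_molecular_solid
from molcsg.primitives import Sphere


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def unit_sphere():
    return Sphere(np.zeros(3), 1.0)


@pytest.fixture(scope="session")
def unit_sphere_mesh(unit_sphere):
    return mesh_solid_boundary(unit_sphere, 0.125)


@pytest.fixture(scope="session")
def dimer_solid():
    return build_molecular_solid(toy_molecule("dimer"), 1.4)


@pytest.fixture(scope="session")
def cluster_solid():
    return build_molecular_solid(toy_molecule("tetra_cluster"), 1.4)


def assert_watertight(mesh, expect_shells=None):
    """Every edge shared by exactly two triangles; Euler count consistent."""
    edges, counts = mesh.edge_counts()
    assert len(counts) > 0, "empty mesh"
    assert np.all(counts == 2), f"{np.sum(counts != 2)} open/non-manifold edges"
    shells = len(np.unique(mesh.shell_labels()))
    chi = mesh.euler_characteristic()
    assert chi % 2 == 0
    assert chi <= 2 * shells
    if expect_shells is not None:
        assert shells == expect_shells
        assert chi == 2 * shells  # genus-0 shells


@pytest.fixture(scope="session")
def watertight_check():
    return assert_watertight
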