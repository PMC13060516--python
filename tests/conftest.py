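import numpy as np
import pytest
import trimesh

from fieldmorph.mesh import TriMesh
from fieldmorph.synthetic import SyntheticHandSpec, make_hand


@pytest.fixture(scope="session")
def hand():
    """Default synthetic hand: (mesh, landmarks, dependency list)."""
    return make_hand(SyntheticHandSpec())


@pytest.fixture(scope="session")
def hand_mesh(hand):
    return hand[0]


@pytest.fixture(scope="session")
def hand_landmarks(hand):
    return hand[1]


@pytest.fixture(scope="session")
def hand_deps(hand):
    return hand[2]


@pytest.fixture(scope="session")
def sphere():
    """Icosphere tilted so no face normal sits exactly at 90 degrees to z."""
    ico = trimesh.creation.icosphere(subdivisions=3)
    c, s = np.cos(0.1), np.sin(0.1)
    R = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    return TriMesh(np.asarray(ico.vertices) @ R.T, np.asarray(ico.faces))


def grid_sheet(n: int = 12, z: float = 0.0) -> TriMesh:
    """Flat unit-spaced triangulated (n x n)-cell sheet in the z plane."""
    xs, ys = np.meshgrid(np.arange(n + 1, dtype=float), np.arange(n + 1, dtype=float))
    V = np.c_[xs.ravel(), ys.ravel(), np.full((n + 1) ** 2, z)]
    F = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            b, c, d = a + 1, a + n + 2, a + n + 1
            F += [[a, b, c], [a, c, d]]
    return TriMesh(V, np.array(F))


@pytest.fixture
def sheet():
    return grid_sheet()
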