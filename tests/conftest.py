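import numpy as np
import pytest

from mrsim.fem import Material, face_traction_loads
from mrsim.registration import MarkerSet
from mrsim.synthetic import gen_block_tetmesh


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def triangle_markers():
    """Minimal trackable marker set: 3 non-collinear markers."""
    return MarkerSet(["M1", "M2", "M3"], [[0, 0, 0], [10, 0, 0], [0, 10, 0]])


@pytest.fixture
def asym_markers():
    """Asymmetric 5-marker cloud with no point symmetry."""
    return MarkerSet(
        ["M1", "M2", "M3", "M4", "M5"],
        [[0, 0, 0], [31, 2, -4], [5, 27, 8], [-12, 9, 23], [17, -19, 11]],
    )


def make_bar(n_axial=6, nu=0.0, e_pa=12e9, length=0.06, side=0.01, force=100.0,
             loading="consistent"):
    """Cantilever bar under an axial end load.

    ``loading="consistent"`` applies the consistent nodal loads of a uniform
    tip traction; with nu = 0 the exact solution (uniform uniaxial stress
    F/A, tip displacement F L / (E A)) then lies in the Tet4 space, so the
    solver must reproduce it to machine precision. ``loading="equal"`` splits
    the end force equally over the tip nodes (the plain point-load idiom).
    """
    mesh = gen_block_tetmesh(n_axial, 2, 2, (length, side, side))
    mesh.material = Material(e_pa, nu)
    mesh.constrained_nodes = {i for i, p in enumerate(mesh.nodes) if p[0] < 1e-12}
    tip_mask = mesh.nodes[:, 0] > length - 1e-12
    if loading == "consistent":
        area = side * side
        mesh.loads = face_traction_loads(mesh, tip_mask, np.array([force / area, 0.0, 0.0]))
    else:
        tip = np.where(tip_mask)[0]
        mesh.loads = {int(i): np.array([force / len(tip), 0.0, 0.0]) for i in tip}
    return mesh, tip_mask


@pytest.fixture
def bar_mesh():
    return make_bar()
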