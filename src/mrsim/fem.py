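"""Static linear-elastic FEM of instrument-on-bone loading, desk scale.

The simulator needs to know the *critical force* — the instrument load above
which the vertebral endplate is at risk — so the force monitor can warn the
trainee. That number comes from a static finite-element analysis: a
tetrahedral solid with isotropic linear-elastic material, fully fixed
constraint nodes, and point loads representing the rasp contact. Because the
problem is linear, one unit-load solve yields the whole load sweep: stresses
scale proportionally with the load magnitude.

Elements are 4-node constant-strain tetrahedra (Tet4). Dirichlet constraints
are imposed by row/column elimination (exact, well-conditioned), never by
penalties. Results carry nodal displacements, per-element stress tensors and
the von Mises equivalent stress used to locate the critical region.

Accuracy note: Tet4 is the simplest solid element; it locks in bending and
needs fine meshes near stress concentrations. It is entirely adequate for
the verification problems (patch test, uniaxial bar) and for desk-scale
sweeps, which is the scope here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import (
    FileFormatError,
    InvalidArgumentError,
    MeshQualityError,
    NoCriticalForceError,
    RigidBodyModeError,
)

__all__ = [
    "Material",
    "TetMesh",
    "FEMResult",
    "solve_static",
    "von_mises",
    "critical_force_sweep",
    "critical_force_bisect",
    "identify_critical_region",
    "assemble_stiffness",
    "read_vtk",
    "write_vtk",
    "read_msh",
    "write_msh",
    "write_result_vtk",
]

#: bone-like placeholder elastic constants (cortical-bone order of magnitude).
#: NOT authoritative biological values — supply measured properties for any
#: quantitative use.
DEFAULT_E_PA = 12e9
DEFAULT_NU = 0.3


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material."""

    young_modulus: float  # Pa
    poisson_ratio: float

    def __post_init__(self):
        if not self.young_modulus > 0:
            raise InvalidArgumentError("Young's modulus must be positive")
        if not (-1.0 < self.poisson_ratio < 0.5):
            raise InvalidArgumentError("Poisson's ratio must lie in (-1, 0.5)")

    @property
    def d_matrix(self) -> np.ndarray:
        """6x6 constitutive matrix in Voigt order (xx, yy, zz, xy, yz, zx)."""
        e, nu = self.young_modulus, self.poisson_ratio
        lam = e * nu / ((1 + nu) * (1 - 2 * nu))
        mu = e / (2 * (1 + nu))
        d = np.zeros((6, 6))
        d[:3, :3] = lam
        d[np.arange(3), np.arange(3)] += 2 * mu
        d[3:, 3:] = np.eye(3) * mu
        return d


@dataclass
class TetMesh:
    """Tetrahedral solid with material, fixed nodes and point loads.

    ``constrained_nodes`` have all three displacement DOFs fixed to zero;
    ``loads`` maps node index -> force vector (N). Elements with negative
    signed volume are re-oriented at construction; zero-volume elements are a
    mesh-quality error.
    """

    nodes: np.ndarray  # (n, 3), mm
    elements: np.ndarray  # (m, 4) int
    material: Material = field(default_factory=lambda: Material(DEFAULT_E_PA, DEFAULT_NU))
    constrained_nodes: set[int] = field(default_factory=set)
    loads: dict[int, np.ndarray] = field(default_factory=dict)
    #: non-zero Dirichlet data: node -> prescribed displacement vector.
    #: (constrained_nodes is the zero-displacement shortcut)
    prescribed: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.elements = np.asarray(self.elements, dtype=int).reshape(-1, 4)
        self.constrained_nodes = set(int(i) for i in self.constrained_nodes)
        self.loads = {int(k): np.asarray(v, dtype=float).reshape(3) for k, v in self.loads.items()}
        self.prescribed = {
            int(k): np.asarray(v, dtype=float).reshape(3) for k, v in self.prescribed.items()
        }
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.nodes)
        ):
            raise InvalidArgumentError("element node indices out of range")
        vols = self.signed_volumes()
        neg = vols < 0
        if np.any(neg):  # orientation fix: swap two nodes of inverted tets
            e = self.elements.copy()
            e[neg, 0], e[neg, 1] = self.elements[neg, 1], self.elements[neg, 0]
            self.elements = e
            vols = self.signed_volumes()
        tiny = np.abs(vols) <= 1e-14 * max(1.0, float(np.abs(vols).max(initial=0.0)))
        if np.any(tiny):
            raise MeshQualityError(
                f"{int(tiny.sum())} degenerate (zero-volume) tetrahedra"
            )
        overlap = self.constrained_nodes & set(self.loads)
        if overlap:
            warnings.warn(
                f"nodes both constrained and loaded: {sorted(overlap)} "
                "(their loads go straight into the reactions)",
                stacklevel=2,
            )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def signed_volumes(self) -> np.ndarray:
        v = self.nodes[self.elements]
        return (
            np.einsum(
                "ij,ij->i",
                np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
                v[:, 3] - v[:, 0],
            )
            / 6.0
        )

    def total_volume(self) -> float:
        return float(self.signed_volumes().sum())

    def load_vector(self) -> np.ndarray:
        f = np.zeros(3 * self.n_nodes)
        for node, vec in self.loads.items():
            f[3 * node : 3 * node + 3] += vec
        return f


@dataclass
class FEMResult:
    """Solution fields of a static solve."""

    displacements: np.ndarray  # (n, 3), same length unit as the mesh
    element_stress: np.ndarray  # (m, 3, 3) symmetric tensors, Pa
    von_mises: np.ndarray  # (m,), Pa
    reactions: np.ndarray  # (n, 3); non-zero only at constrained nodes

    @property
    def max_von_mises(self) -> float:
        return float(self.von_mises.max())

    @property
    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.displacements, axis=1).max())


def _element_b_and_volume(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Strain-displacement matrix (6x12) and volume of one Tet4 element."""
    m = np.column_stack([np.ones(4), coords])
    det = np.linalg.det(m)
    vol = det / 6.0
    cinv = np.linalg.inv(m)
    grads = cinv[1:4, :]  # (3, 4): d N_i / d(x,y,z) in column i
    b = np.zeros((6, 12))
    for i in range(4):
        bx, by, bz = grads[:, i]
        c = 3 * i
        b[0, c] = bx
        b[1, c + 1] = by
        b[2, c + 2] = bz
        b[3, c] = by
        b[3, c + 1] = bx
        b[4, c + 1] = bz
        b[4, c + 2] = by
        b[5, c] = bz
        b[5, c + 2] = bx
    return b, vol


def assemble_stiffness(mesh: TetMesh) -> sp.csr_matrix:
    """Global stiffness matrix (no constraints applied)."""
    d = mesh.material.d_matrix
    n_dof = 3 * mesh.n_nodes
    rows, cols, vals = [], [], []
    for elem in mesh.elements:
        b, vol = _element_b_and_volume(mesh.nodes[elem])
        if vol <= 0:
            raise MeshQualityError("inverted element encountered during assembly")
        ke = vol * (b.T @ d @ b)
        dofs = np.concatenate([3 * elem[i] + np.arange(3) for i in range(4)])
        rr, cc = np.meshgrid(dofs, dofs, indexing="ij")
        rows.append(rr.ravel())
        cols.append(cc.ravel())
        vals.append(ke.ravel())
    k = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_dof, n_dof),
    )
    return k.tocsr()


def _nullspace_dimension(kff: sp.csr_matrix) -> int:
    n = kff.shape[0]
    if n == 0:
        return 0
    dense_limit = 600
    if n <= dense_limit:
        w = np.linalg.eigvalsh(kff.toarray())
    else:
        k = min(12, n - 1)
        w = spla.eigsh(kff, k=k, sigma=0, which="LM", return_eigenvectors=False)
    scale = float(np.abs(w).max(initial=1.0))
    return int(np.sum(np.abs(w) < 1e-9 * scale))


def solve_static(mesh: TetMesh) -> FEMResult:
    """Solve ``K u = f`` with Dirichlet constraints eliminated.

    Raises :class:`RigidBodyModeError` (reporting the null-space dimension)
    when the constraints do not remove all rigid-body modes.
    """
    k = assemble_stiffness(mesh)
    f = mesh.load_vector()
    n_dof = 3 * mesh.n_nodes
    fixed = np.zeros(n_dof, dtype=bool)
    for node in mesh.constrained_nodes:
        fixed[3 * node : 3 * node + 3] = True
    u = np.zeros(n_dof)
    for node, disp in mesh.prescribed.items():
        fixed[3 * node : 3 * node + 3] = True
        u[3 * node : 3 * node + 3] = disp
    free = ~fixed
    kff = k[free][:, free].tocsc()
    rhs = f[free] - k[free][:, fixed] @ u[fixed]
    if kff.shape[0] > 0:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", spla.MatrixRankWarning)
                uf = spla.spsolve(kff, rhs)
        except (RuntimeError, spla.MatrixRankWarning):
            dim = _nullspace_dimension(kff)
            raise RigidBodyModeError(
                f"singular stiffness: {dim} unconstrained rigid-body mode(s)", dim
            ) from None
        if not np.all(np.isfinite(uf)):
            dim = _nullspace_dimension(kff)
            raise RigidBodyModeError(
                f"singular stiffness: {dim} unconstrained rigid-body mode(s)", dim
            )
        # guard against a numerically singular factorization that "succeeded"
        resid = np.linalg.norm(kff @ uf - rhs)
        ref = np.linalg.norm(rhs)
        if ref > 0 and resid > 1e-6 * ref:
            dim = _nullspace_dimension(kff)
            raise RigidBodyModeError(
                f"singular stiffness: {dim} unconstrained rigid-body mode(s)", dim
            )
        u[free] = uf

    reactions = (k @ u - f).reshape(-1, 3)
    # zero out the (numerically tiny) entries at free nodes
    free_nodes = ~fixed.reshape(-1, 3)[:, 0]
    reactions[free_nodes] = 0.0

    d = mesh.material.d_matrix
    stresses = np.zeros((mesh.n_elements, 3, 3))
    vm = np.zeros(mesh.n_elements)
    for ei, elem in enumerate(mesh.elements):
        b, _ = _element_b_and_volume(mesh.nodes[elem])
        ue = u.reshape(-1, 3)[elem].ravel()
        s = d @ (b @ ue)  # Voigt (xx, yy, zz, xy, yz, zx)
        t = np.array(
            [[s[0], s[3], s[5]], [s[3], s[1], s[4]], [s[5], s[4], s[2]]]
        )
        stresses[ei] = t
        vm[ei] = von_mises(t)
    return FEMResult(u.reshape(-1, 3), stresses, vm, reactions)


def von_mises(stress) -> float:
    """von Mises equivalent stress of a symmetric 3x3 stress tensor."""
    s = np.asarray(stress, dtype=float).reshape(3, 3)
    return float(
        np.sqrt(
            0.5
            * (
                (s[0, 0] - s[1, 1]) ** 2
                + (s[1, 1] - s[2, 2]) ** 2
                + (s[2, 2] - s[0, 0]) ** 2
            )
            + 3.0 * (s[0, 1] ** 2 + s[1, 2] ** 2 + s[0, 2] ** 2)
        )
    )


def critical_force_sweep(
    mesh: TetMesh,
    load_pattern: dict[int, np.ndarray],
    yield_stress: float,
    f_max: float | None = None,
    tol: float = 1e-6,
) -> float:
    """Smallest load magnitude whose peak von Mises reaches the yield stress.

    ``load_pattern`` is a unit force distribution (its magnitudes are scaled
    uniformly). For a linear problem one unit solve suffices:
    ``F_crit = yield_stress / max_vm_per_unit_load``. The bisection fallback
    (:func:`critical_force_bisect`) exists for future nonlinear extensions
    and agrees with this formula within ``tol`` on linear problems.
    """
    if not yield_stress > 0:
        raise InvalidArgumentError("yield stress must be positive")
    unit_mesh = TetMesh(
        mesh.nodes, mesh.elements, mesh.material, set(mesh.constrained_nodes), dict(load_pattern)
    )
    result = solve_static(unit_mesh)
    peak = result.max_von_mises
    if peak <= 0:
        raise NoCriticalForceError("unit load produces zero stress everywhere")
    f_crit = yield_stress / peak
    if f_max is not None and f_crit > f_max:
        raise NoCriticalForceError(
            f"critical force {f_crit:.3g} N exceeds the sweep limit {f_max:.3g} N"
        )
    return f_crit


def critical_force_bisect(
    mesh: TetMesh,
    load_pattern: dict[int, np.ndarray],
    yield_stress: float,
    f_max: float,
    tol: float,
    max_iter: int = 60,
) -> float:
    """Bisection search for the critical force (re-solving at each magnitude).

    On linear problems this must agree with :func:`critical_force_sweep`; it
    is the drop-in procedure for a future nonlinear solver where stress no
    longer scales with load.
    """

    def peak_vm(magnitude: float) -> float:
        scaled = {k: magnitude * np.asarray(v, dtype=float) for k, v in load_pattern.items()}
        m = TetMesh(
            mesh.nodes, mesh.elements, mesh.material, set(mesh.constrained_nodes), scaled
        )
        return solve_static(m).max_von_mises

    if peak_vm(f_max) < yield_stress:
        raise NoCriticalForceError(
            f"yield stress not reached anywhere below f_max={f_max:.3g} N"
        )
    lo, hi = 0.0, f_max
    it = 0
    while hi - lo > tol and it < max_iter:
        mid = 0.5 * (lo + hi)
        if peak_vm(mid) >= yield_stress:
            hi = mid
        else:
            lo = mid
        it += 1
    return 0.5 * (lo + hi)


def identify_critical_region(result: FEMResult, fraction: float = 0.05) -> np.ndarray:
    """Element indices in the top ``fraction`` of the von Mises distribution.

    Elements whose stress is >= the (1 - fraction) quantile are returned;
    with uniform stress the >= comparison includes every element once the
    quantile equals that stress. Deterministic for a given result.
    """
    if not (0.0 < fraction <= 1.0):
        raise InvalidArgumentError("fraction must be in (0, 1]")
    q = float(np.quantile(result.von_mises, 1.0 - fraction))
    # tiny relative slack so a numerically uniform field counts as one tie
    slack = 1e-9 * float(result.von_mises.max(initial=0.0))
    return np.nonzero(result.von_mises >= q - slack)[0]


def face_traction_loads(
    mesh: TetMesh, node_mask: np.ndarray, traction: np.ndarray
) -> dict[int, np.ndarray]:
    """Consistent nodal loads for a uniform traction on selected boundary faces.

    A tet face is loaded when all three of its nodes satisfy ``node_mask``
    (e.g. "lies on the x = L plane"). For linear tetrahedra the consistent
    load lumps one third of ``traction * face_area`` onto each face node.
    """
    node_mask = np.asarray(node_mask, dtype=bool)
    traction = np.asarray(traction, dtype=float).reshape(3)
    loads: dict[int, np.ndarray] = {}
    face_local = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    for elem in mesh.elements:
        for a, b, c in face_local:
            tri = elem[[a, b, c]]
            if not node_mask[tri].all():
                continue
            p = mesh.nodes[tri]
            area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
            for node in tri:
                loads.setdefault(int(node), np.zeros(3))
                loads[int(node)] += traction * (area / 3.0)
    return loads


# ---------------------------------------------------------------------------
# text-format mesh I/O: legacy ASCII VTK unstructured grids and Gmsh MSH 2.2


def write_vtk(mesh: TetMesh, path) -> None:
    """Write the mesh as a legacy ASCII VTK unstructured grid (cell type 10)."""
    lines = [
        "# vtk DataFile Version 3.0",
        "mrsim tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for p in mesh.nodes:
        lines.append(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    lines.append(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}")
    for e in mesh.elements:
        lines.append("4 " + " ".join(str(i) for i in e))
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend(["10"] * mesh.n_elements)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk(path, material: Material | None = None) -> TetMesh:
    """Read a legacy ASCII VTK unstructured grid of tetrahedra."""
    tokens = open(path).read().split()
    tl = [t.upper() for t in tokens]
    try:
        if "ASCII" not in tl:
            raise FileFormatError(f"{path}: only ASCII legacy VTK is supported")
        i = tl.index("POINTS")
        n_pts = int(tokens[i + 1])
        coords = np.array(tokens[i + 3 : i + 3 + 3 * n_pts], dtype=float).reshape(-1, 3)
        j = tl.index("CELLS")
        n_cells = int(tokens[j + 1])
        k = j + 3
        cells = []
        for _ in range(n_cells):
            nv = int(tokens[k])
            if nv != 4:
                raise FileFormatError(f"{path}: non-tetrahedral cell with {nv} vertices")
            cells.append([int(v) for v in tokens[k + 1 : k + 5]])
            k += 5
        ct = tl.index("CELL_TYPES")
        types = tokens[ct + 2 : ct + 2 + n_cells]
        if any(t != "10" for t in types):
            raise FileFormatError(f"{path}: cells must all be VTK_TETRA (type 10)")
    except (ValueError, IndexError) as e:
        raise FileFormatError(f"{path}: malformed VTK unstructured grid: {e}") from e
    return TetMesh(coords, np.array(cells, dtype=int),
                   material or Material(DEFAULT_E_PA, DEFAULT_NU))


def write_msh(mesh: TetMesh, path) -> None:
    """Write the mesh in Gmsh MSH 2.2 ASCII format (element type 4)."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_nodes)]
    for i, p in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    lines += ["$EndNodes", "$Elements", str(mesh.n_elements)]
    for i, e in enumerate(mesh.elements, start=1):
        lines.append(f"{i} 4 2 0 1 " + " ".join(str(v + 1) for v in e))
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path, material: Material | None = None) -> TetMesh:
    """Read a Gmsh MSH 2.2 ASCII file, keeping only tetrahedra (type 4)."""
    lines = [ln.strip() for ln in open(path)]
    try:
        ni = lines.index("$Nodes")
        n_nodes = int(lines[ni + 1])
        id_map: dict[int, int] = {}
        coords = np.zeros((n_nodes, 3))
        for k in range(n_nodes):
            parts = lines[ni + 2 + k].split()
            id_map[int(parts[0])] = k
            coords[k] = [float(v) for v in parts[1:4]]
        ei = lines.index("$Elements")
        n_elem = int(lines[ei + 1])
        cells = []
        for k in range(n_elem):
            parts = lines[ei + 2 + k].split()
            etype = int(parts[1])
            if etype != 4:
                continue
            ntags = int(parts[2])
            node_ids = [int(v) for v in parts[3 + ntags :]]
            cells.append([id_map[v] for v in node_ids])
    except (ValueError, IndexError) as e:
        raise FileFormatError(f"{path}: malformed MSH 2.2 file: {e}") from e
    if not cells:
        raise FileFormatError(f"{path}: no tetrahedral elements found")
    return TetMesh(coords, np.array(cells, dtype=int),
                   material or Material(DEFAULT_E_PA, DEFAULT_NU))


def write_result_vtk(mesh: TetMesh, result: FEMResult, path) -> None:
    """Write displacements (point vectors) and von Mises (cell scalars) as VTK."""
    write_vtk(mesh, path)
    with open(path, "a") as fh:
        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        fh.write("VECTORS displacement double\n")
        for d in result.displacements:
            fh.write(f"{d[0]:.9g} {d[1]:.9g} {d[2]:.9g}\n")
        fh.write(f"CELL_DATA {mesh.n_elements}\n")
        fh.write("SCALARS von_mises double 1\nLOOKUP_TABLE default\n")
        for v in result.von_mises:
            fh.write(f"{v:.9g}\n")
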