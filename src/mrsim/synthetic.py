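"""Deterministic generators for every input class of the toolkit.

No capture hardware or deposited dataset is needed to exercise the pipeline:
marker clouds, rigid trajectories with noise and dropout, block tetrahedral
meshes and ellipsoid surface meshes are all generated from explicit seeds.
Every generator is a pure function of its arguments, so identical calls
produce identical fixtures on any platform.

What is emulated: a rigid object carrying asymmetric retro-reflective
markers moving smoothly through a capture volume, observed at a fixed rate
with isotropic Gaussian position noise and Bernoulli frame dropout. What is
*not* emulated: camera projection geometry, marker-merging/occlusion
physics, calibration residuals, reflective clutter — so passing recovery
tests bounds algorithmic error, not real-rig error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import FeasibilityError, InvalidArgumentError
from .fem import Material, TetMesh, DEFAULT_E_PA, DEFAULT_NU
from .geom import RigidTransform, expmap_to_quaternion, quaternion_to_expmap
from .motion import MotionFrame, MotionStream, RawPose
from .registration import MarkerSet, SurfaceMesh, fit_rigid_transform

__all__ = [
    "TrajectorySpec",
    "gen_rigid_trajectory",
    "gen_marker_cloud",
    "gen_block_tetmesh",
    "gen_ellipsoid_mesh",
    "has_point_symmetry",
]


@dataclass(frozen=True)
class TrajectorySpec:
    """Parametric rigid path through the capture volume.

    The path is a smooth quasi-periodic sweep: translation components are
    incommensurate sinusoids of amplitude ``translation_amplitude`` (mm) and
    the orientation precesses at ``angular_velocity`` (rad/s) about a slowly
    wandering axis — rich enough to exercise every rotation quadrant without
    discontinuities.
    """

    n_frames: int = 200
    rate: float = 200.0  # Hz, capture rate of the optical system
    translation_amplitude: float = 100.0  # mm
    angular_velocity: float = 1.0  # rad/s
    noise_sigma: float = 0.0  # mm, iid Gaussian on marker positions
    dropout_rate: float = 0.0  # Bernoulli probability a frame is occluded
    seed: int = 0

    def __post_init__(self):
        if not self.rate > 0:
            raise InvalidArgumentError("rate must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise InvalidArgumentError("dropout_rate must be in [0, 1)")
        if self.n_frames < 1:
            raise InvalidArgumentError("need at least one frame")


def _pose_at(spec: TrajectorySpec, t: float) -> RigidTransform:
    a = spec.translation_amplitude
    trans = a * np.array(
        [np.sin(0.9 * t), np.sin(0.63 * t + 1.0), np.sin(1.31 * t + 2.0)]
    )
    # precessing axis; angle grows linearly then wraps through the expmap
    axis = np.array([np.cos(0.21 * t), np.sin(0.17 * t + 0.5), 0.6])
    axis = axis / np.linalg.norm(axis)
    angle = np.mod(spec.angular_velocity * t, 2 * np.pi)
    if angle > np.pi:
        angle -= 2 * np.pi
    return RigidTransform(expmap_to_quaternion(axis * angle), trans)


def gen_rigid_trajectory(
    spec: TrajectorySpec, markers: MarkerSet, object_name: str = "object"
) -> tuple[MotionStream, list[RigidTransform | None]]:
    """Simulate a capture session of one rigid marker-carrying object.

    Per frame, marker world positions are ``pose(root-relative) + noise``;
    the delivered object pose is re-solved from those (noisy) markers by
    least squares, exactly as an optical tracker does. Frames dropped by the
    Bernoulli occlusion model carry no pose and all-invisible markers.

    Returns the stream and the ground-truth pose per frame (None on dropped
    frames).
    """
    if len(markers) < 3 or markers.is_collinear():
        raise InvalidArgumentError("marker set must be trackable (>=3, non-collinear)")
    rng = np.random.default_rng(spec.seed)
    frames: list[MotionFrame] = []
    truth: list[RigidTransform | None] = []
    dt = 1.0 / spec.rate
    for k in range(spec.n_frames):
        t = k * dt
        pose = _pose_at(spec, t)
        dropped = bool(rng.random() < spec.dropout_rate)
        frame = MotionFrame(k, t)
        if dropped:
            frame.marker_visibility = {n: False for n in markers.names}
            truth.append(None)
        else:
            world = pose.apply(markers.positions)
            if spec.noise_sigma > 0:
                world = world + rng.normal(0.0, spec.noise_sigma, world.shape)
            fitted = fit_rigid_transform(markers.positions, world)
            frame.poses[object_name] = RawPose(
                fitted.transform.translation,
                quaternion_to_expmap(fitted.transform.rotation),
            )
            frame.marker_visibility = {n: True for n in markers.names}
            truth.append(pose)
        frames.append(frame)
    return MotionStream(frames, nominal_rate=spec.rate), truth


def _distance_matrix(points: np.ndarray) -> np.ndarray:
    return np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)


def has_point_symmetry(points: np.ndarray, tol: float = 1e-6) -> bool:
    """True if a nontrivial orthogonal transform maps the set onto itself.

    Any such symmetry induces a permutation preserving the pairwise distance
    matrix; candidate permutations are enumerated by backtracking on the
    distance matrix (cheap for the small sets used as marker clouds), then
    verified by solving the orthogonal Procrustes alignment of the centered
    set onto its permutation (reflections allowed: no det correction).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(pts)
    c = pts - pts.mean(axis=0)
    dm = _distance_matrix(c)

    def candidates(mapping: list[int], used: set[int]):
        i = len(mapping)
        if i == n:
            yield list(mapping)
            return
        for j in range(n):
            if j in used:
                continue
            if all(abs(dm[i, k] - dm[j, mapping[k]]) < tol * 10 for k in range(i)):
                mapping.append(j)
                used.add(j)
                yield from candidates(mapping, used)
                mapping.pop()
                used.remove(j)

    scale = max(1.0, float(np.abs(c).max()))
    for perm in candidates([], set()):
        if perm == list(range(n)):
            continue
        # best orthogonal Q (det +1 or -1) mapping c -> c[perm]
        h = c.T @ c[perm]
        u, _, vt = np.linalg.svd(h)
        q = vt.T @ u.T
        if np.linalg.norm(c @ q.T - c[perm]) < tol * scale * n:
            return True
    return False


def gen_marker_cloud(
    n: int,
    min_separation: float = 20.0,
    seed: int = 0,
    box_size: float = 100.0,
    radius: float = 0.5,
    max_attempts: int = 2000,
) -> MarkerSet:
    """Sample an asymmetric, well-separated marker cloud.

    Rejection-samples ``n`` points in a cube of side ``box_size`` (mm) until
    every pairwise distance is >= ``min_separation``, the set is
    non-collinear, and it has no nontrivial point symmetry (asymmetric
    placement is what lets a tracker tell left from right and avoid
    upside-down solutions).
    """
    if n < 3:
        raise InvalidArgumentError("a trackable cloud needs n >= 3")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        pts = rng.uniform(-box_size / 2, box_size / 2, size=(n, 3))
        dm = _distance_matrix(pts)
        iu = np.triu_indices(n, k=1)
        if dm[iu].min() < min_separation:
            continue
        ms = MarkerSet([f"M{i + 1}" for i in range(n)], pts, radius=radius)
        if ms.is_collinear():
            continue
        if has_point_symmetry(pts):
            continue
        return ms
    raise FeasibilityError(
        f"could not pack {n} markers with separation {min_separation} in a "
        f"{box_size} mm box after {max_attempts} attempts"
    )


# 6-tet Kuhn subdivision of the unit cube: every cube face is split the same
# way along the main diagonal, so adjacent cubes share conforming faces
_KUHN_TETS = [
    (0, 1, 3, 7),
    (0, 1, 7, 5),
    (0, 5, 7, 4),
    (0, 3, 2, 7),
    (0, 2, 6, 7),
    (0, 6, 4, 7),
]


def gen_block_tetmesh(
    nx: int,
    ny: int,
    nz: int,
    dims: tuple[float, float, float] = (1.0, 1.0, 1.0),
    material: Material | None = None,
) -> TetMesh:
    """Structured tetrahedral block: ``(nx+1)(ny+1)(nz+1)`` nodes and
    ``6 nx ny nz`` positive-volume elements filling a box of size ``dims``."""
    if min(nx, ny, nz) < 1:
        raise InvalidArgumentError("element counts must be >= 1")
    lx, ly, lz = dims
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    nodes = np.array([[x, y, z] for x in xs for y in ys for z in zs])
    elements = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corner = {}
                for b, (di, dj, dk) in enumerate(itertools.product((0, 1), repeat=3)):
                    # bit order: di = bit2, dj = bit1, dk = bit0
                    corner[(di << 2) | (dj << 1) | dk] = nid(i + di, j + dj, k + dk)
                for tet in _KUHN_TETS:
                    elements.append([corner[v] for v in tet])
    return TetMesh(
        nodes,
        np.array(elements, dtype=int),
        material or Material(DEFAULT_E_PA, DEFAULT_NU),
    )


def gen_ellipsoid_mesh(a: float, b: float, c: float, subdivisions: int = 3) -> SurfaceMesh:
    """Watertight ellipsoid surface: an icosphere scaled by the semi-axes.

    Every vertex lies exactly on the ellipsoid (x/a)^2+(y/b)^2+(z/c)^2 = 1
    up to floating-point rounding.
    """
    if min(a, b, c) <= 0:
        raise InvalidArgumentError("semi-axes must be positive")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(ico.vertices, dtype=float)
    # re-normalize defensively, then scale
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    return SurfaceMesh(v * np.array([a, b, c]), np.asarray(ico.faces, dtype=int))
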