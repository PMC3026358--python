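"""Rigid registration between captured markers and virtual models.

Two complementary workflows are supported, mirroring how a tracked physical
object is aligned with its virtual counterpart in a mixed-reality scene:

* **forward**: pick feature points directly on the virtual surface and emit a
  tracking model (see :mod:`mrsim.vsk`) whose markers are the picked points —
  the physical markers are then attached at the corresponding spots;
* **reverse**: record marker positions with the optical system, manually
  associate each captured marker with a point on the virtual surface, and
  solve the least-squares rigid alignment (Kabsch/SVD with reflection
  correction).

Per-pair residuals are always reported so a bad alignment can be spotted and
re-registered quickly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import (
    FileFormatError,
    InvalidArgumentError,
    InvalidPickError,
    UnderdeterminedError,
)
from .geom import RigidTransform

__all__ = [
    "MarkerSet",
    "Correspondence",
    "RegistrationResult",
    "SurfaceMesh",
    "fit_rigid_transform",
    "register_captured",
    "place_virtual_markers",
    "compute_extreme_points",
    "plane_cross_section",
    "MarkerProximityWarning",
]

#: default marker sphere radius written to tracking-model files (same value
#: the optical system expects for the retro-reflective spheres)
DEFAULT_MARKER_RADIUS = 0.5

# ratio of second-largest to largest singular value of the centered cloud
# below which the points are treated as collinear (rank <= 1)
_COLLINEAR_RTOL = 1e-9


class MarkerProximityWarning(UserWarning):
    """Two markers closer than the minimum separation; tracking accuracy of
    densely packed markers degrades."""


@dataclass
class MarkerSet:
    """Named markers with positions relative to the root segment (mm)."""

    names: list[str]
    positions: np.ndarray  # (n, 3)
    radius: float = DEFAULT_MARKER_RADIUS

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.names) != len(self.positions):
            raise InvalidArgumentError("marker names and positions differ in length")
        if len(set(self.names)) != len(self.names):
            raise InvalidArgumentError("marker names must be unique")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidArgumentError("marker positions must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def position_of(self, name: str) -> np.ndarray:
        try:
            return self.positions[self.names.index(name)]
        except ValueError:
            raise InvalidArgumentError(f"unknown marker name {name!r}") from None

    def is_collinear(self) -> bool:
        return _is_collinear(self.positions)


@dataclass
class Correspondence:
    """User-supplied pairing of captured marker names to virtual-surface points."""

    marker_names: list[str]
    virtual_points: np.ndarray  # (n, 3), model frame

    def __post_init__(self):
        self.virtual_points = np.asarray(self.virtual_points, dtype=float).reshape(-1, 3)
        if len(self.marker_names) != len(self.virtual_points):
            raise InvalidArgumentError("correspondence names and points differ in length")

    def __len__(self) -> int:
        return len(self.marker_names)

    # plain-text interchange: versioned header, one `marker,vx,vy,vz` row per pair
    HEADER = "# mrsim-correspondence v1"

    def write_csv(self, path) -> None:
        lines = [self.HEADER, "marker,vx,vy,vz"]
        for name, p in zip(self.marker_names, self.virtual_points):
            lines.append(f"{name},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_csv(cls, path) -> "Correspondence":
        raw = Path(path).read_text().splitlines()
        rows = [ln for ln in raw if ln.strip() and not ln.startswith("#")]
        if not rows or rows[0].split(",")[0] != "marker":
            raise FileFormatError(f"{path}: missing 'marker,vx,vy,vz' header")
        names, pts = [], []
        for ln in rows[1:]:
            parts = ln.split(",")
            if len(parts) != 4:
                raise FileFormatError(f"{path}: bad correspondence row {ln!r}")
            names.append(parts[0].strip())
            pts.append([float(v) for v in parts[1:]])
        return cls(names, np.array(pts, dtype=float).reshape(-1, 3))


@dataclass
class RegistrationResult:
    """Least-squares alignment plus the residual report used to judge it."""

    transform: RigidTransform
    rms_residual: float
    per_pair_residuals: np.ndarray

    def __post_init__(self):
        self.per_pair_residuals = np.asarray(self.per_pair_residuals, dtype=float)

    def worst_pair(self) -> int:
        """Index of the pair with the largest residual."""
        return int(np.argmax(self.per_pair_residuals))


@dataclass
class SurfaceMesh:
    """Triangle surface mesh (vertices + faces), loadable from OBJ/STL/PLY."""

    vertices: np.ndarray  # (n, 3)
    faces: np.ndarray  # (m, 3) int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise InvalidArgumentError("face indices out of range")

    @classmethod
    def load(cls, path) -> "SurfaceMesh":
        """Read OBJ/STL/PLY; zero-area faces are dropped at load time."""
        tm = trimesh.load(str(path), force="mesh", process=False)
        mesh = cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=int))
        return mesh.drop_degenerate_faces()

    def save(self, path) -> None:
        trimesh.Trimesh(self.vertices, self.faces, process=False).export(str(path))

    def drop_degenerate_faces(self, area_eps: float = 1e-12) -> "SurfaceMesh":
        v = self.vertices[self.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
        )
        return SurfaceMesh(self.vertices, self.faces[areas > area_eps])

    def bounding_box_diagonal(self) -> float:
        if len(self.vertices) == 0:
            return 0.0
        return float(np.linalg.norm(self.vertices.max(0) - self.vertices.min(0)))

    def edges(self) -> np.ndarray:
        """Unique undirected edges as (k, 2) index pairs."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)


def _is_collinear(points: np.ndarray) -> bool:
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return bool(s[0] == 0.0 or s[1] < _COLLINEAR_RTOL * s[0])


def fit_rigid_transform(src, dst) -> RegistrationResult:
    """Least-squares rigid alignment: find (R, t) minimizing
    ``sum ||R src_i + t - dst_i||^2`` by SVD of the cross-covariance.

    A reflection (det = -1) is corrected by flipping the singular direction
    with the smallest singular value, so the result is always a proper
    rotation. Raises :class:`UnderdeterminedError` for fewer than three pairs
    or a collinear source/target configuration, for which the rotation about
    the common axis is arbitrary.
    """
    src = np.asarray(src, dtype=float).reshape(-1, 3)
    dst = np.asarray(dst, dtype=float).reshape(-1, 3)
    if len(src) != len(dst):
        raise InvalidArgumentError(f"point counts differ: {len(src)} vs {len(dst)}")
    if len(src) < 3:
        raise UnderdeterminedError(
            f"{len(src)} pairs cannot determine a unique rotation (minimum 3)"
        )
    if not (np.all(np.isfinite(src)) and np.all(np.isfinite(dst))):
        raise InvalidArgumentError("points must be finite")
    if _is_collinear(src) or _is_collinear(dst):
        raise UnderdeterminedError("collinear point configuration: rotation not unique")

    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0.0:  # fully degenerate cross-covariance; treat as proper
        d = 1.0
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    t = cd - rot @ cs
    transform = RigidTransform.from_matrix(rot, t)
    res = np.linalg.norm(transform.apply(src) - dst, axis=1)
    return RegistrationResult(transform, float(np.sqrt(np.mean(res**2))), res)


def register_captured(
    markers: MarkerSet, corr: Correspondence, mesh: SurfaceMesh | None = None
) -> RegistrationResult:
    """Reverse registration: align the virtual model to the captured markers.

    ``markers`` holds the captured marker positions (capture frame, mm);
    ``corr`` maps marker names to points on the virtual surface. The returned
    transform maps the **model frame to the capture frame**, and per-pair
    residuals support the decision to re-register a bad alignment.
    """
    if len(corr) < 3:
        raise UnderdeterminedError("correspondence needs at least 3 pairs")
    captured = np.array([markers.position_of(n) for n in corr.marker_names])
    return fit_rigid_transform(corr.virtual_points, captured)


def _closest_point_on_triangle(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on a single triangle (Ericson's real-time method)."""
    a, b, c = tri
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        return a + (d1 / (d1 - d3)) * ab
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        return a + (d2 / (d2 - d6)) * ac
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        return b + ((d4 - d3) / ((d4 - d3) + (d5 - d6))) * (c - b)
    denom = va + vb + vc
    v, w = vb / denom, vc / denom
    return a + v * ab + w * ac


def closest_surface_point(mesh: SurfaceMesh, p) -> tuple[np.ndarray, float]:
    """Nearest point on the mesh surface and its distance (exhaustive scan)."""
    p = np.asarray(p, dtype=float).reshape(3)
    tris = mesh.vertices[mesh.faces]
    best, best_d = None, np.inf
    for tri in tris:
        q = _closest_point_on_triangle(p, tri)
        d = float(np.linalg.norm(q - p))
        if d < best_d:
            best, best_d = q, d
    if best is None:
        raise InvalidArgumentError("mesh has no faces")
    return best, best_d


def place_virtual_markers(
    mesh: SurfaceMesh,
    picks,
    radius: float = DEFAULT_MARKER_RADIUS,
    snap_tolerance: float | None = None,
    min_separation: float = 0.0,
    name_prefix: str = "M",
) -> MarkerSet:
    """Forward registration: turn surface picks into a marker set.

    Each pick is snapped to its nearest surface point; a pick farther than
    ``snap_tolerance`` (default 1% of the bounding-box diagonal) raises
    :class:`InvalidPickError`. Marker coordinates are expressed relative to
    the root segment at the model origin, so the set can be serialized
    directly as a tracking model. A :class:`MarkerProximityWarning` is emitted
    when any two markers end up closer than ``min_separation`` — crowding
    markers degrades tracking accuracy.
    """
    picks = np.asarray(picks, dtype=float).reshape(-1, 3)
    if snap_tolerance is None:
        snap_tolerance = 0.01 * mesh.bounding_box_diagonal()
    snapped = []
    for i, p in enumerate(picks):
        q, d = closest_surface_point(mesh, p)
        if d > snap_tolerance:
            raise InvalidPickError(
                f"pick {i} is {d:.4g} from the surface (tolerance {snap_tolerance:.4g})"
            )
        snapped.append(q)
    pos = np.array(snapped).reshape(-1, 3)
    if min_separation > 0 and len(pos) > 1:
        dists = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        iu = np.triu_indices(len(pos), k=1)
        if np.any(dists[iu] < min_separation):
            warnings.warn(
                f"markers closer than minimum separation {min_separation}",
                MarkerProximityWarning,
                stacklevel=2,
            )
    names = [f"{name_prefix}{i + 1}" for i in range(len(pos))]
    return MarkerSet(names, pos, radius=radius)


def compute_extreme_points(mesh: SurfaceMesh) -> dict[str, np.ndarray]:
    """Extreme mesh vertices along each axis, labelled ``min_x`` .. ``max_z``.

    These six feature points anchor the reference-plane construction used when
    registering roughly ellipsoidal objects. Ties resolve to the lowest vertex
    index.
    """
    if len(mesh.vertices) == 0:
        raise InvalidArgumentError("empty mesh")
    out: dict[str, np.ndarray] = {}
    for ax, label in enumerate("xyz"):
        out[f"min_{label}"] = mesh.vertices[int(np.argmin(mesh.vertices[:, ax]))].copy()
        out[f"max_{label}"] = mesh.vertices[int(np.argmax(mesh.vertices[:, ax]))].copy()
    return out


def plane_cross_section(mesh: SurfaceMesh, plane_point, plane_normal) -> np.ndarray:
    """Intersection points of mesh edges with a plane.

    Returns an (k, 3) array of points where unique mesh edges cross the plane
    (one point per crossing edge; vertices lying exactly on the plane are
    included once). Empty when nothing crosses.
    """
    n = np.asarray(plane_normal, dtype=float).reshape(3)
    nn = np.linalg.norm(n)
    if nn == 0 or not np.isfinite(nn):
        raise InvalidArgumentError("plane normal must be non-zero and finite")
    n = n / nn
    p0 = np.asarray(plane_point, dtype=float).reshape(3)
    d = (mesh.vertices - p0) @ n  # signed distances
    pts = []
    eps = 1e-12 * max(1.0, float(np.abs(d).max(initial=0.0)))
    on_plane = np.abs(d) <= eps
    for vi in np.nonzero(on_plane)[0]:
        pts.append(mesh.vertices[vi])
    for i, j in mesh.edges():
        di, dj = d[i], d[j]
        if on_plane[i] or on_plane[j]:
            continue
        if di * dj < 0:
            t = di / (di - dj)
            pts.append(mesh.vertices[i] + t * (mesh.vertices[j] - mesh.vertices[i]))
    if not pts:
        return np.empty((0, 3))
    return np.array(pts)
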