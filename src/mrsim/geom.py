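"""Rotation representations and rigid-transform algebra.

Conventions used everywhere in the toolkit:

* quaternions are **scalar-first** arrays ``[w, x, y, z]`` with unit norm and
  canonical sign ``w >= 0``;
* exponential-map rotation vectors are in **radians**, direction = axis,
  magnitude = angle, canonicalized to magnitude <= pi;
* coordinate frames are right-handed;
* points are plain ``(3,)`` float arrays (millimetres in the capture domain,
  model units elsewhere; containers record their unit).

The optical tracker delivers per-frame rotations as exponential maps; the
scene graph consumes quaternions, so the conversions here sit on the hot path
of every processed frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "expmap_to_quaternion",
    "quaternion_to_expmap",
    "quat_multiply",
    "quat_conjugate",
    "quat_rotate",
    "quat_to_matrix",
    "matrix_to_quat",
    "quat_slerp",
    "geodesic_angle",
    "canonical_quat",
    "RigidTransform",
]

# below this rotation angle (radians) the sinc-like terms are evaluated by
# their Taylor series to avoid dividing by a vanishing norm
_SMALL_ANGLE = 1e-8


def _as_vec3(v, name: str = "vector") -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise InvalidArgumentError(f"{name} has non-finite components: {a}")
    return a


def canonical_quat(q) -> np.ndarray:
    """Normalize to unit length and flip sign so that w >= 0."""
    q = np.asarray(q, dtype=float).reshape(4)
    n = np.linalg.norm(q)
    if not np.isfinite(n) or n == 0.0:
        raise InvalidArgumentError("quaternion must be finite and non-zero")
    q = q / n
    if q[0] < 0.0:
        q = -q
    return q


def expmap_to_quaternion(r) -> np.ndarray:
    """Convert an exponential-map rotation vector to a unit quaternion.

    The quaternion encodes a rotation by ``||r||`` radians about ``r/||r||``.
    Angles below 1e-8 rad use a 2nd-order Taylor expansion of
    ``sin(theta/2)/theta`` so the axis division never blows up.
    """
    r = _as_vec3(r, "rotation vector")
    theta = float(np.linalg.norm(r))
    half = 0.5 * theta
    if theta < _SMALL_ANGLE:
        # sin(t/2)/t = 1/2 - t^2/48 + O(t^4)
        k = 0.5 - theta * theta / 48.0
    else:
        k = np.sin(half) / theta
    q = np.empty(4)
    q[0] = np.cos(half)
    q[1:] = k * r
    return canonical_quat(q)


def quaternion_to_expmap(q) -> np.ndarray:
    """Inverse conversion; returns the canonical vector with magnitude <= pi.

    Raises if the quaternion is not unit within 1e-6.
    """
    q = np.asarray(q, dtype=float).reshape(4)
    n = np.linalg.norm(q)
    if abs(n - 1.0) > 1e-6:
        raise InvalidArgumentError(f"quaternion norm {n:.3e} is not 1")
    q = canonical_quat(q)
    s = np.linalg.norm(q[1:])
    theta = 2.0 * np.arctan2(s, q[0])  # in [0, pi]; stable for tiny angles
    if s < _SMALL_ANGLE:
        # theta / sin(theta/2) -> 2 as theta -> 0
        return 2.0 * q[1:]
    return (theta / s) * q[1:]


def quat_multiply(a, b) -> np.ndarray:
    """Hamilton product a*b (composition: a applied after b)."""
    aw, ax, ay, az = np.asarray(a, dtype=float).reshape(4)
    bw, bx, by, bz = np.asarray(b, dtype=float).reshape(4)
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def quat_conjugate(q) -> np.ndarray:
    q = np.asarray(q, dtype=float).reshape(4)
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_rotate(q, p) -> np.ndarray:
    """Rotate point(s) p by unit quaternion q. p may be (3,) or (n,3)."""
    q = np.asarray(q, dtype=float).reshape(4)
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    w, v = q[0], q[1:]
    # r' = r + 2 w (v x r) + 2 v x (v x r)
    cv = np.cross(np.broadcast_to(v, pts.shape), pts)
    out = pts + 2.0 * w * cv + 2.0 * np.cross(np.broadcast_to(v, pts.shape), cv)
    return out[0] if single else out


def quat_to_matrix(q) -> np.ndarray:
    """3x3 rotation matrix of a unit quaternion."""
    w, x, y, z = canonical_quat(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def matrix_to_quat(m) -> np.ndarray:
    """Unit quaternion of a proper rotation matrix (Shepperd's method)."""
    m = np.asarray(m, dtype=float).reshape(3, 3)
    t = np.trace(m)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2.0
        q = np.array(
            [0.25 * s, (m[2, 1] - m[1, 2]) / s, (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(m)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(max(0.0, 1.0 + m[i, i] - m[j, j] - m[k, k])) * 2.0
        q = np.empty(4)
        q[0] = (m[k, j] - m[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (m[j, i] + m[i, j]) / s
        q[1 + k] = (m[k, i] + m[i, k]) / s
    return canonical_quat(q)


def geodesic_angle(qa, qb) -> float:
    """Geodesic rotation distance (radians) between two unit quaternions.

    Evaluated via the chordal distance (``4 asin(d/2)`` with d the smaller of
    ``||qa -/+ qb||``), which stays accurate for nearly identical rotations
    where an arccos of the dot product would lose half the significant digits.
    """
    qa = canonical_quat(qa)
    qb = canonical_quat(qb)
    d = min(float(np.linalg.norm(qa - qb)), float(np.linalg.norm(qa + qb)))
    return 4.0 * np.arcsin(min(1.0, 0.5 * d))


def quat_slerp(qa, qb, t: float) -> np.ndarray:
    """Spherical linear interpolation from qa (t=0) to qb (t=1), shortest arc."""
    qa = canonical_quat(qa)
    qb = canonical_quat(qb)
    dot = float(np.dot(qa, qb))
    if dot < 0.0:
        qb, dot = -qb, -dot
    if dot > 1.0 - 1e-12:
        return canonical_quat(qa + t * (qb - qa))
    omega = np.arccos(min(1.0, dot))
    so = np.sin(omega)
    return canonical_quat(
        (np.sin((1.0 - t) * omega) / so) * qa + (np.sin(t * omega) / so) * qb
    )


@dataclass(frozen=True)
class RigidTransform:
    """Rotation-then-translation map ``p -> R p + t``.

    Used both for registration results (model frame -> capture frame) and for
    per-frame object poses.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "rotation", canonical_quat(self.rotation))
        object.__setattr__(self, "translation", _as_vec3(self.translation, "translation"))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, rot: np.ndarray, trans) -> "RigidTransform":
        return cls(matrix_to_quat(rot), trans)

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix form."""
        m = np.eye(4)
        m[:3, :3] = quat_to_matrix(self.rotation)
        m[:3, 3] = self.translation
        return m

    def apply(self, p) -> np.ndarray:
        """Apply to a point (3,) or a cloud (n,3)."""
        return quat_rotate(self.rotation, p) + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self.compose(other)).apply(p) == self.apply(other.apply(p))."""
        return RigidTransform(
            quat_multiply(self.rotation, other.rotation),
            quat_rotate(self.rotation, other.translation) + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        qi = quat_conjugate(self.rotation)
        return RigidTransform(qi, -quat_rotate(qi, self.translation))


def apply_transform(t: RigidTransform, p) -> np.ndarray:
    """Functional form of :meth:`RigidTransform.apply`."""
    return t.apply(p)
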