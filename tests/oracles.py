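"""Independent reference implementations used only to check the package.

Each oracle takes a different computational route than the code under test:
Rodrigues' rotation formula for exponential maps, Horn's closed-form
quaternion-eigenvector absolute orientation (vs the package's SVD route),
and plain brute-force scans.
"""

from __future__ import annotations

import numpy as np


def rodrigues_matrix(rotvec: np.ndarray) -> np.ndarray:
    """Rotation matrix from an exponential map via Rodrigues' formula."""
    r = np.asarray(rotvec, dtype=float)
    theta = np.linalg.norm(r)
    if theta < 1e-30:
        return np.eye(3)
    k = r / theta
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)


def horn_absolute_orientation(src: np.ndarray, dst: np.ndarray):
    """Horn's closed-form solution of the absolute orientation problem.

    Returns (R, t) minimizing sum ||R src_i + t - dst_i||^2 via the maximal
    eigenvector of the 4x4 quaternion profile matrix.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    cs, cd = src.mean(0), dst.mean(0)
    a, b = src - cs, dst - cd
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    n = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    w, v = np.linalg.eigh(n)
    q = v[:, np.argmax(w)]  # unit quaternion, scalar first
    w0, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w0 * z), 2 * (x * z + w0 * y)],
            [2 * (x * y + w0 * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w0 * x)],
            [2 * (x * z - w0 * y), 2 * (y * z + w0 * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, cd - rot @ cs


def count_upcrossings(forces: np.ndarray, threshold: float) -> int:
    """Brute-force count of threshold up-crossings (strictly greater)."""
    above = forces > threshold
    count = int(above[0])
    for prev, cur in zip(above, above[1:]):
        if cur and not prev:
            count += 1
    return count


def onepole_steady_amplitude(alpha: float, period: int = 2, n: int = 4000) -> float:
    """Steady-state output amplitude of the one-pole smoother for a square
    wave of the given period (period=2 is the Nyquist alternation)."""
    x = np.tile(np.repeat([1.0, -1.0], period // 2), n // period + 1)[:n]
    y = np.empty_like(x)
    y[0] = x[0]
    for k in range(1, n):
        y[k] = y[k - 1] + alpha * (x[k] - y[k - 1])
    return float(np.abs(y[n // 2 :]).max())


def rotation_angle_between(ra: np.ndarray, rb: np.ndarray) -> float:
    """Geodesic angle between two rotation matrices (atan2 form: stable
    near zero where arccos of the trace would be inaccurate)."""
    r = ra.T @ rb
    skew = 0.5 * np.array([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]])
    s = np.linalg.norm(skew)
    c = (np.trace(r) - 1.0) / 2.0
    return float(np.arctan2(s, c))
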