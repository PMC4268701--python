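"""Batched rigid-body geometry kernels (SO(3) exponential/logarithm maps).

All public functions accept arrays with an arbitrary number of leading batch
dimensions; rotation matrices are stored as ``(..., 3, 3)`` proper orthogonal
arrays and rotation vectors as ``(..., 3)`` axis-angle vectors in radians.
Numerically delicate branches (angle near 0 and near pi) use Taylor series /
quaternion extraction so that downstream force gradients stay smooth.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def hat(w: np.ndarray) -> np.ndarray:
    """Skew-symmetric matrix [w]x such that [w]x @ v = w x v."""
    w = np.asarray(w, dtype=float)
    out = np.zeros(w.shape[:-1] + (3, 3))
    wx, wy, wz = w[..., 0], w[..., 1], w[..., 2]
    out[..., 0, 1] = -wz
    out[..., 0, 2] = wy
    out[..., 1, 0] = wz
    out[..., 1, 2] = -wx
    out[..., 2, 0] = -wy
    out[..., 2, 1] = wx
    return out


def exp_so3(w: np.ndarray) -> np.ndarray:
    """Rodrigues exponential map: rotation vector -> rotation matrix."""
    w = np.asarray(w, dtype=float)
    theta = np.linalg.norm(w, axis=-1)
    W = hat(w)
    W2 = W @ W
    t = theta[..., None, None]
    small = theta < 1e-6
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(small, 1.0 - theta**2 / 6.0, np.sin(theta) / np.where(small, 1.0, theta))
        b = np.where(
            small,
            0.5 - theta**2 / 24.0,
            (1.0 - np.cos(theta)) / np.where(small, 1.0, theta**2),
        )
    eye = np.broadcast_to(np.eye(3), W.shape)
    return eye + a[..., None, None] * W + b[..., None, None] * W2


def quat_from_matrix(R: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) from rotation matrix, batched and robust."""
    R = np.asarray(R, dtype=float)
    batch = R.shape[:-2]
    Rf = R.reshape(-1, 3, 3)
    n = Rf.shape[0]
    q = np.empty((n, 4))
    tr = Rf[:, 0, 0] + Rf[:, 1, 1] + Rf[:, 2, 2]
    # Shepperd's method: pick the largest of (trace, R00, R11, R22) per item.
    choice = np.argmax(
        np.stack([tr, Rf[:, 0, 0], Rf[:, 1, 1], Rf[:, 2, 2]], axis=1), axis=1
    )

    m = choice == 0
    if np.any(m):
        s = np.sqrt(tr[m] + 1.0) * 2.0
        q[m, 0] = 0.25 * s
        q[m, 1] = (Rf[m, 2, 1] - Rf[m, 1, 2]) / s
        q[m, 2] = (Rf[m, 0, 2] - Rf[m, 2, 0]) / s
        q[m, 3] = (Rf[m, 1, 0] - Rf[m, 0, 1]) / s
    for i, (j, k) in zip((1, 2, 3), ((1, 2), (2, 0), (0, 1))):
        m = choice == i
        if not np.any(m):
            continue
        ii = i - 1
        s = np.sqrt(1.0 + Rf[m, ii, ii] - Rf[m, j, j] - Rf[m, k, k]) * 2.0
        q[m, 0] = (Rf[m, k, j] - Rf[m, j, k]) / s
        q[m, ii + 1] = 0.25 * s
        q[m, j + 1] = (Rf[m, j, ii] + Rf[m, ii, j]) / s
        q[m, k + 1] = (Rf[m, k, ii] + Rf[m, ii, k]) / s
    # canonical sign: w >= 0 so the encoded angle is <= pi
    q[q[:, 0] < 0] *= -1.0
    norm = np.linalg.norm(q, axis=1, keepdims=True)
    q /= norm
    return q.reshape(batch + (4,))


def matrix_from_quat(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    q = q / np.linalg.norm(q, axis=-1, keepdims=True)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    R = np.empty(q.shape[:-1] + (3, 3))
    R[..., 0, 0] = 1 - 2 * (y * y + z * z)
    R[..., 0, 1] = 2 * (x * y - z * w)
    R[..., 0, 2] = 2 * (x * z + y * w)
    R[..., 1, 0] = 2 * (x * y + z * w)
    R[..., 1, 1] = 1 - 2 * (x * x + z * z)
    R[..., 1, 2] = 2 * (y * z - x * w)
    R[..., 2, 0] = 2 * (x * z - y * w)
    R[..., 2, 1] = 2 * (y * z + x * w)
    R[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def log_so3(R: np.ndarray) -> np.ndarray:
    """Rotation vector of R with |theta| <= pi, via quaternion extraction."""
    q = quat_from_matrix(R)
    qv = q[..., 1:]
    qw = q[..., 0]
    s = np.linalg.norm(qv, axis=-1)
    theta = 2.0 * np.arctan2(s, qw)
    small = s < 1e-12
    scale = np.where(small, 2.0, theta / np.where(small, 1.0, s))
    return qv * scale[..., None]


def left_jacobian(w: np.ndarray) -> np.ndarray:
    """Left Jacobian J_l of SO(3): d(exp(w)) = [J_l(w) dw]x exp(w)."""
    w = np.asarray(w, dtype=float)
    theta = np.linalg.norm(w, axis=-1)
    W = hat(w)
    W2 = W @ W
    small = theta < 1e-6
    th = np.where(small, 1.0, theta)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(small, 0.5 - theta**2 / 24.0, (1.0 - np.cos(theta)) / th**2)
        b = np.where(small, 1.0 / 6.0 - theta**2 / 120.0, (theta - np.sin(theta)) / th**3)
    eye = np.broadcast_to(np.eye(3), W.shape)
    return eye + a[..., None, None] * W + b[..., None, None] * W2


def left_jacobian_inv(w: np.ndarray) -> np.ndarray:
    """Inverse left Jacobian: d log(exp(dw) exp(w)) = J_l^{-1}(w) dw."""
    w = np.asarray(w, dtype=float)
    theta = np.linalg.norm(w, axis=-1)
    W = hat(w)
    W2 = W @ W
    small = theta < 1e-6
    th = np.where(small, 1.0, theta)
    with np.errstate(invalid="ignore", divide="ignore"):
        half = 0.5 * theta
        cot = np.where(small, 1.0, half / np.tan(np.where(small, 1.0, half)))
        c = np.where(
            small,
            1.0 / 12.0 + theta**2 / 720.0,
            (1.0 - cot) / th**2,
        )
    eye = np.broadcast_to(np.eye(3), W.shape)
    return eye - 0.5 * W + c[..., None, None] * W2


def normalize_rotations(R: np.ndarray) -> np.ndarray:
    """Re-orthonormalize drifting rotation matrices via quaternion round trip."""
    return matrix_from_quat(quat_from_matrix(R))


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a to unit vector b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    v = np.cross(a, b)
    c = np.clip(np.sum(a * b, axis=-1), -1.0, 1.0)
    s = np.linalg.norm(v, axis=-1)
    angle = np.arctan2(s, c)
    # degenerate antiparallel case: rotate about any axis orthogonal to a
    if np.isscalar(angle) or angle.ndim == 0:
        if s < 1e-12:
            if c > 0:
                return np.eye(3)
            axis = _orthogonal(a)
            return exp_so3(axis * np.pi)
        return exp_so3(v / s * angle)
    axis = np.where(s[..., None] > 1e-12, v / np.where(s[..., None] > 1e-12, s[..., None], 1.0), 0.0)
    out = exp_so3(axis * angle[..., None])
    anti = (s < 1e-12) & (c < 0)
    if np.any(anti):
        idx = np.nonzero(anti)
        for flat in zip(*idx):
            out[flat] = exp_so3(_orthogonal(a[flat]) * np.pi)
    return out


def _orthogonal(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    trial = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(a, trial)
    return v / np.linalg.norm(v)


def midpoint_rotation(Ra: np.ndarray, Rb: np.ndarray) -> np.ndarray:
    """Geodesic midpoint of two rotations (slerp at t=1/2)."""
    rel = np.swapaxes(Ra, -1, -2) @ Rb
    return Ra @ exp_so3(0.5 * log_so3(rel))


def orthonormal_frame(e3: np.ndarray, hint: np.ndarray | None = None) -> np.ndarray:
    """Right-handed frame whose third column is e3; first column follows hint."""
    e3 = np.asarray(e3, dtype=float)
    e3 = e3 / np.linalg.norm(e3)
    if hint is None:
        hint = np.array([1.0, 0.0, 0.0]) if abs(e3[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = hint - np.dot(hint, e3) * e3
    n = np.linalg.norm(e1)
    if n < 1e-12:
        e1 = _orthogonal(e3)
    else:
        e1 = e1 / n
    e2 = np.cross(e3, e1)
    return np.stack([e1, e2, e3], axis=-1)
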