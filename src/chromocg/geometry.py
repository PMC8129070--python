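"""Quaternion and reference-frame helpers.

Quaternions are stored scalar-first ``(w, x, y, z)`` and always unit norm.
A frame is a (position, quaternion) pair; the rotation matrix columns are
the frame's x/y/z axes expressed in the lab frame.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "quat_identity",
    "quat_normalize",
    "quat_multiply",
    "quat_to_matrix",
    "matrix_to_quat",
    "quat_rotate",
    "quat_from_rotvec",
    "random_quaternion",
]


def quat_identity() -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def _to_scipy(q: np.ndarray) -> Rotation:
    q = np.asarray(q, dtype=float)
    return Rotation.from_quat(np.roll(q, -1, axis=-1))  # scalar-last for scipy


def _from_scipy(rot: Rotation) -> np.ndarray:
    return np.roll(rot.as_quat(), 1, axis=-1)


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1 * q2 (apply q2's rotation first)."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    w1, x1, y1, z1 = q1[..., 0], q1[..., 1], q1[..., 2], q1[..., 3]
    w2, x2, y2, z2 = q2[..., 0], q2[..., 1], q2[..., 2], q2[..., 3]
    out = np.empty(np.broadcast(q1, q2).shape)
    out[..., 0] = w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2
    out[..., 1] = w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2
    out[..., 2] = w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2
    out[..., 3] = w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2
    return out


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    return _to_scipy(q).as_matrix()


def matrix_to_quat(m: np.ndarray) -> np.ndarray:
    return _from_scipy(Rotation.from_matrix(m))


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v (body frame) into the lab frame."""
    return _to_scipy(q).apply(np.asarray(v, dtype=float))


def quat_from_rotvec(rotvec: np.ndarray) -> np.ndarray:
    """Quaternion for a rotation vector (axis * angle, radians)."""
    return _from_scipy(Rotation.from_rotvec(np.asarray(rotvec, dtype=float)))


def random_quaternion(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


# -- vectorised pure-numpy versions (hot paths; scipy Rotation object
#    construction is too slow inside integrator loops) ----------------------

def quat_conj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.empty(np.broadcast(a, b).shape)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def quat_rotate_vec(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vectors v by quaternions q; shapes broadcast on the batch axis."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    w = q[..., :1]
    u = q[..., 1:]
    uv = _cross(u, v)
    return v + 2.0 * (w * uv + _cross(u, uv))


def rotvec_to_quat(rv: np.ndarray) -> np.ndarray:
    """Vectorised exponential map (rotation vector in radians -> quaternion)."""
    rv = np.asarray(rv, dtype=float)
    angle = np.linalg.norm(rv, axis=-1, keepdims=True)
    small = angle < 1e-12
    half = 0.5 * angle
    # sin(x)/x with series fallback for tiny angles
    sinc = np.where(small, 0.5 - angle**2 / 48.0, np.sin(half) / np.where(small, 1.0, angle))
    w = np.cos(half)
    return np.concatenate([w, sinc * rv], axis=-1)


def quat_to_rotvec(q: np.ndarray) -> np.ndarray:
    """Vectorised logarithm map (quaternion -> rotation vector, radians)."""
    q = np.asarray(q, dtype=float)
    q = np.where(q[..., :1] < 0, -q, q)  # canonical hemisphere
    n = np.linalg.norm(q[..., 1:], axis=-1, keepdims=True)
    angle = 2.0 * np.arctan2(n, q[..., :1])
    scale = np.where(n < 1e-12, 2.0 / np.clip(q[..., :1], 1e-12, None), angle / np.where(n < 1e-12, 1.0, n))
    return scale * q[..., 1:]
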