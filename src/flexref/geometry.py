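"""Small geometric primitives shared across modules.

All coordinates are Cartesian angstroms; angles are returned in radians
unless a function name says otherwise.
"""

from __future__ import annotations

import numpy as np


def norm(v: np.ndarray) -> np.ndarray:
    return np.linalg.norm(v, axis=-1)


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Angle a-b-c (vertex at b), vectorized over leading axes."""
    u = a - b
    v = c - b
    cosang = np.sum(u * v, axis=-1) / (norm(u) * norm(v))
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed dihedral p0-p1-p2-p3 in (-pi, pi], IUPAC sign convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / norm(b1)[..., None])
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.arctan2(y, x)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, theta: float, phi: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) = theta and
    dihedral(a,b,c,d) = phi (natural extension reference frame)."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(phi),
        -bond * np.sin(theta) * np.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch(mobile: np.ndarray, ref: np.ndarray, weights=None):
    """Least-squares rigid superposition of `mobile` onto `ref`.

    Returns (R, t) such that mobile @ R.T + t best matches ref.
    """
    mobile = np.asarray(mobile, float)
    ref = np.asarray(ref, float)
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, float)
    w = w / w.sum()
    mu_m = (w[:, None] * mobile).sum(0)
    mu_r = (w[:, None] * ref).sum(0)
    A = (ref - mu_r).T @ (w[:, None] * (mobile - mu_m))
    U, _, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = mu_r - R @ mu_m
    return R, t


def superpose(mobile: np.ndarray, ref: np.ndarray, weights=None) -> np.ndarray:
    """Return `mobile` rigidly superposed onto `ref`."""
    R, t = kabsch(mobile, ref, weights)
    return mobile @ R.T + t


def rotation_about_axis(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation by theta about `axis`."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
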