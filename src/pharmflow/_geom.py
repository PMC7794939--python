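"""Small geometry helpers shared across modules (Å units throughout)."""
from __future__ import annotations

import numpy as np


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping points P onto Q.

    Returns rotation matrix R (3x3, proper) and translation t such that
    ``P @ R.T + t`` minimizes the RMSD to Q. Degenerate inputs (fewer than
    3 points, collinear sets) still yield a valid, if non-unique, transform.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - cp @ R.T
    return R, t


def apply_rigid(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (no-fit) root-mean-square deviation between matched coordinates."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane through >= 3 points (SVD)."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    n = vt[2]
    return n / np.linalg.norm(n)


def interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two plane normals in degrees, folded into [0, 90]."""
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, in degrees."""
    v1 = np.asarray(a, float) - np.asarray(b, float)
    v2 = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
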