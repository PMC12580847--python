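"""Rigid-body geometry utilities: Kabsch superposition and rotation sampling.

Rotations here are always proper (det = +1). Disallowing reflections is a
deliberate modelling choice carried through alignment and RMSD: a mirror-image
(enantiomer) prediction must score a strictly positive residual.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError

__all__ = ["kabsch_rotation", "align", "superimpose_rmsd", "random_rotation"]


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Proper rotation R (3×3, det=+1) minimizing ‖p Rᵀ − q‖_F for centered p, q.

    Rows of p rotated by R (i.e. ``p @ R.T``) best match rows of q. Degenerate
    (collinear/coplanar) inputs are handled by the SVD sign-correction branch,
    which forces det(R) = +1.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise InputError(f"point sets must share an N×3 shape, got {p.shape} vs {q.shape}")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:  # fully degenerate overlap matrix: break tie toward +1
        d = 1.0
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def align(x0: np.ndarray, x1: np.ndarray) -> np.ndarray:
    """Center x0 and rotate it (proper rotation only) onto centered x1.

    Returns R·(x0 − centroid(x0)) with R the Kabsch optimum; x1 is not
    modified — the caller centers it separately. Centroids are unweighted.
    """
    x0 = np.asarray(x0, dtype=np.float64)
    x1 = np.asarray(x1, dtype=np.float64)
    if x0.shape != x1.shape:
        raise InputError(f"shape mismatch: {x0.shape} vs {x1.shape}")
    x0c = x0 - x0.mean(axis=0)
    x1c = x1 - x1.mean(axis=0)
    r = kabsch_rotation(x0c, x1c)
    return x0c @ r.T


def superimpose_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD between p and q over proper rigid motions (rotation + translation)."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise InputError(f"shape mismatch: {p.shape} vs {q.shape}")
    if p.shape[0] < 1:
        raise InputError("need at least one atom")
    qc = q - q.mean(axis=0)
    pa = align(p, q)
    return float(np.sqrt(np.mean(np.sum((pa - qc) ** 2, axis=1))))


def random_rotation(rng: np.random.Generator, proper: bool = True) -> np.ndarray:
    """Haar-ish random orthogonal 3×3 via QR; det forced to ±1 as requested."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if proper and np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    elif not proper and np.linalg.det(q) > 0:
        q[:, 0] = -q[:, 0]
    return q
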