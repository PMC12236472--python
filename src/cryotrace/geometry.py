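"""Rigid-body superposition utilities (Kabsch algorithm)."""

from __future__ import annotations

import numpy as np


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Both are (n, 3) arrays of paired points, n ≥ 1.  Returns
    ``(transformed_mobile, rmsd, (R, t))`` where ``R`` is the rotation and
    ``t`` the translation such that ``mobile @ R.T + t ≈ target``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("superpose expects matching (n, 3) arrays")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    P = mobile - cm
    Q = target - ct
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = P @ R.T + ct
    t = ct - cm @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return moved, rmsd, (R, t)


def apply_transform(points: np.ndarray, transform) -> np.ndarray:
    R, t = transform
    return np.asarray(points, dtype=float) @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
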