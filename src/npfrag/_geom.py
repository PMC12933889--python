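"""Shared rigid-body geometry: Kabsch superposition and plane fitting."""

from __future__ import annotations

import numpy as np


def kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``moving`` onto ``target``.

    Returns (rotation, translation, rmsd) such that
    ``moving @ rotation.T + translation`` best matches ``target``.  The
    rotation is proper (det = +1).
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.shape != target.shape or moving.shape[0] < 3:
        raise ValueError("need two equal coordinate sets with >= 3 points")
    mc = moving.mean(axis=0)
    tc = target.mean(axis=0)
    h = (moving - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tc - rot @ mc
    moved = moving @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return rot, trans, rmsd


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through ``points``: returns (centroid, unit normal).

    Raises ValueError for fewer than 3 points or (near-)collinear input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear: the two largest singular values cannot both be non-trivial
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise ValueError("points are collinear; plane undefined")
    return centroid, vt[2]


def plane_distances(points: np.ndarray, centroid: np.ndarray, normal: np.ndarray) -> np.ndarray:
    return np.abs((np.asarray(points, dtype=float) - centroid) @ normal)
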