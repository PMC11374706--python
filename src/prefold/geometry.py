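"""Low-level vector geometry: dihedrals, internal-coordinate atom placement,
Kabsch superposition and RMSD.

All coordinates are (..., 3) float arrays in Å.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "place_atom",
    "dihedral",
    "bond_angle",
    "rotation_about_axis",
    "kabsch_rotation",
    "superpose",
    "rmsd_after_superposition",
]


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               length: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given atoms A, B, C and internal coordinates.

    Natural-extension-of-reference-frame construction: ``length`` is the C-D
    bond (Å), ``angle`` the B-C-D angle and ``torsion`` the A-B-C-D dihedral,
    both in radians.
    """
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        # colinear support atoms: pick an arbitrary perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, helper)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array([
        -length * np.cos(angle),
        length * np.sin(angle) * np.cos(torsion),
        length * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in radians, IUPAC sign convention."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.arctan2(y, x))


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in radians."""
    u = np.asarray(p0) - np.asarray(p1)
    v = np.asarray(p2) - np.asarray(p1)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix for a rotation of ``angle`` radians about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    t = 1.0 - c
    return np.array([
        [t * x * x + c, t * x * y - s * z, t * x * z + s * y],
        [t * x * y + s * z, t * y * y + c, t * y * z - s * x],
        [t * x * z - s * y, t * y * z + s * x, t * z * z + c],
    ])


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix mapping centred ``mobile`` onto centred ``target``."""
    h = mobile.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    return u @ diag @ vt


def superpose(mobile: np.ndarray, target: np.ndarray,
              apply_to: np.ndarray | None = None) -> np.ndarray:
    """Least-squares superpose ``mobile`` onto ``target``.

    Returns the transformed copy of ``apply_to`` (default: ``mobile``).
    """
    if apply_to is None:
        apply_to = mobile
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot = kabsch_rotation(mobile - mc, target - tc)
    return (apply_to - mc) @ rot + tc


def rmsd_after_superposition(a: np.ndarray, b: np.ndarray) -> float:
    """Best-fit (Kabsch) RMSD between two coordinate sets of equal size, Å."""
    a2 = superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((a2 - b) ** 2, axis=1))))
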