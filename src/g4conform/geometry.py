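"""Low-level vector geometry shared by all analysis modules.

All angles are reported in degrees. Dihedrals follow the IUPAC sign
convention (looking from p2 to p3, clockwise rotation of the far bond is
positive) and are mapped onto [0, 360).
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "GeometryError",
    "dihedral",
    "signed_dihedral",
    "angle",
    "wrap360",
    "wrap180",
    "circular_mean",
    "rotation_about_axis",
    "random_rigid_transform",
    "plane_normal",
]


class GeometryError(ValueError):
    """Raised for degenerate geometric input (collinear or coincident points)."""


def wrap360(x):
    """Map an angle (degrees) onto [0, 360)."""
    if np.ndim(x):
        y = np.asarray(x) % 360.0
        return np.where(y == 360.0, 0.0, y)  # tiny negatives round up to 360.0
    y = float(x % 360.0)
    return 0.0 if y == 360.0 else y


def wrap180(x):
    """Map an angle (degrees) onto (-180, 180]."""
    y = (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0
    y = np.where(y == -180.0, 180.0, y)
    return float(y) if np.ndim(x) == 0 else y


def signed_dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle in (-180, 180] for four points, IUPAC sign convention."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if min(np.linalg.norm(b1), np.linalg.norm(b2), np.linalg.norm(b3)) < 1e-9:
        raise GeometryError("coincident consecutive points in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("collinear points in dihedral")
    m = np.cross(b2 / np.linalg.norm(b2), n1)
    x = n1 @ n2
    y = m @ n2
    return float(np.degrees(np.arctan2(y, x)))


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle on [0, 360)."""
    return wrap360(signed_dihedral(p1, p2, p3, p4))


def angle(p1, p2, p3) -> float:
    """Bond angle p1-p2-p3 in degrees, on [0, 180]."""
    v1 = np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)
    v2 = np.asarray(p3, dtype=float) - np.asarray(p2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise GeometryError("coincident points in angle")
    return float(np.degrees(np.arccos(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))))


def circular_mean(angles_deg) -> float:
    """Mean of angles in degrees, correct across the 0/360 wrap, on [0, 360)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return wrap360(np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))))


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix for a right-handed rotation about ``axis``."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    K = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)


def random_rigid_transform(rng: np.random.Generator):
    """A random proper rotation and translation, for invariance checks."""
    axis = rng.normal(size=3)
    R = rotation_about_axis(axis, rng.uniform(0.0, 360.0))
    t = rng.uniform(-50.0, 50.0, size=3)
    return R, t


def plane_normal(points) -> np.ndarray:
    """Unit normal of the least-squares plane through ``points`` (n x 3)."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise GeometryError("plane fit needs at least 3 points")
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[-2] < 1e-9:
        raise GeometryError("points are collinear; plane undefined")
    return vt[-1]
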