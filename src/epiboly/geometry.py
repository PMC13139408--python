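"""Spherical geometry utilities.

The embryo frame is fixed: center at the origin, animal pole on +z, vegetal
pole on -z.  The polar angle phi runs from 0 at the animal pole to pi at the
vegetal pole; the azimuth theta is measured from +x and wraps modulo 2*pi.
Percent-epiboly p in [0, 1] is the fraction of the embryo surface covered by
the EVL, related to the leading-edge polar angle by p = (1 - cos phi) / 2.
"""

from __future__ import annotations

import math

import numpy as np

#: below this value of sin(phi) the meridian tangent is treated as undefined
POLE_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised for pole-degenerate tangents and rank-deficient plane fits."""


# ---------------------------------------------------------------------------
# staging conversions
# ---------------------------------------------------------------------------

def stage_to_polar(p: float) -> float:
    """Polar angle of the leading edge at percent-epiboly ``p`` (fraction).

    phi = arccos(1 - 2p).  p = 0.5 is the equator (phi = pi/2).
    """
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"percent-epiboly must be in [0, 1], got {p}")
    return math.acos(1.0 - 2.0 * p)


def polar_to_stage(phi: float) -> float:
    """Inverse of :func:`stage_to_polar`: p = (1 - cos phi) / 2."""
    phi = float(phi)
    if not 0.0 <= phi <= math.pi:
        raise ValueError(f"polar angle must be in [0, pi], got {phi}")
    return (1.0 - math.cos(phi)) / 2.0


def spherical_cap_area(radius: float, p: float) -> float:
    """Area of the spherical cap covering fraction ``p`` of a sphere.

    The cap from the pole down to stage p has area 4*pi*R^2*p, since p is by
    definition the covered area fraction.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    return 4.0 * math.pi * radius * radius * p


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def polar_angles(points: np.ndarray) -> np.ndarray:
    """Polar angle phi of each 3D point relative to the origin."""
    pts = np.atleast_2d(points)
    r = np.linalg.norm(pts, axis=1)
    return np.arccos(np.clip(pts[:, 2] / r, -1.0, 1.0))


def azimuth_angles(points: np.ndarray) -> np.ndarray:
    """Azimuth theta in [0, 2*pi) of each 3D point."""
    pts = np.atleast_2d(points)
    return np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2.0 * math.pi)


def wrapped_dtheta(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray | float:
    """Shortest signed azimuthal difference a - b, in (-pi, pi]."""
    d = np.mod(np.asarray(a) - np.asarray(b), 2.0 * math.pi)
    return np.where(d > math.pi, d - 2.0 * math.pi, d)


def vegetal_tangent(pos: np.ndarray, center: np.ndarray | None = None) -> np.ndarray:
    """Unit tangent to the embryo surface at ``pos``, toward the vegetal pole.

    The vector lies in the meridian plane, is orthogonal to the radial
    direction, and points toward increasing polar angle:
    t = (cos(phi) * r_hat - z_hat) / sin(phi).
    """
    pos = np.asarray(pos, dtype=float)
    if center is not None:
        pos = pos - np.asarray(center, dtype=float)
    r = np.linalg.norm(pos)
    if r == 0.0:
        raise DegenerateGeometryError("position coincides with the center")
    rhat = pos / r
    cos_phi = np.clip(rhat[2], -1.0, 1.0)
    sin_phi = math.sqrt(max(0.0, 1.0 - cos_phi * cos_phi))
    if sin_phi < POLE_TOL:
        raise DegenerateGeometryError("meridian tangent undefined at a pole")
    t = (cos_phi * rhat - np.array([0.0, 0.0, 1.0])) / sin_phi
    return t


def vegetal_tangents(points: np.ndarray) -> np.ndarray:
    """Vectorized :func:`vegetal_tangent` for an (n, 3) array."""
    pts = np.asarray(points, dtype=float)
    r = np.linalg.norm(pts, axis=1, keepdims=True)
    rhat = pts / r
    cos_phi = np.clip(rhat[:, 2], -1.0, 1.0)
    sin_phi = np.sqrt(np.maximum(0.0, 1.0 - cos_phi**2))
    if np.any(sin_phi < POLE_TOL):
        raise DegenerateGeometryError("meridian tangent undefined at a pole")
    t = cos_phi[:, None] * rhat
    t[:, 2] -= 1.0
    return t / sin_phi[:, None]


# ---------------------------------------------------------------------------
# best-fit plane and frame rotation
# ---------------------------------------------------------------------------

def best_fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Upward unit normal of the least-squares plane through ``points``.

    The plane passes through the centroid; the normal is the singular vector
    of the centered coordinates with the smallest singular value, sign-flipped
    so its z-component is non-negative.  Raises for < 3 points or collinear
    input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points in 3D")
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise DegenerateGeometryError("points are collinear or coincident")
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    return normal


def rotation_to_vertical(normal: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping the unit vector ``normal`` onto +z."""
    n = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise DegenerateGeometryError("zero-length normal")
    n = n / norm
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(n @ z, -1.0, 1.0))
    axis = np.cross(n, z)
    s = np.linalg.norm(axis)
    if s < 1e-15:
        # already vertical (or anti-vertical: rotate about x by pi)
        if c > 0:
            return np.eye(3)
        return np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    k = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + s * k + (1.0 - c) * (k @ k)


def rotate_frame(points: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Rigidly rotate ``points`` so that ``normal`` becomes vertical (+z)."""
    rot = rotation_to_vertical(normal)
    return np.asarray(points, dtype=float) @ rot.T
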