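"""Small geometric primitives shared by the interaction detectors.

All coordinates are cartesian, in angstroms.  Angles are returned in degrees.
Ring normals have an arbitrary sign, so every angular test against a normal
folds the angle onto [0, 90] via :func:`folded_angle`.
"""
from __future__ import annotations

import numpy as np

from .errors import GeometryError

#: slack added to every "<= cutoff" comparison so that geometries constructed
#: exactly at a cutoff are not lost to floating-point round-off.
EPS = 1e-9


def distance(a, b) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def angle_deg(a, b, c) -> float:
    """Angle A-B-C at vertex ``b``, in degrees."""
    v1 = np.asarray(a, float) - np.asarray(b, float)
    v2 = np.asarray(c, float) - np.asarray(b, float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise GeometryError("zero-length vector in angle computation")
    cosv = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosv)))


def vector_angle_deg(u, v) -> float:
    """Angle between two vectors, in degrees, in [0, 180]."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise GeometryError("zero-length vector")
    cosv = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosv)))


def folded_angle(theta: float) -> float:
    """Fold an angle onto [0, 90] (sign of ring normals is arbitrary)."""
    theta = theta % 180.0
    return min(theta, 180.0 - theta)


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Dihedral angle over the four points, in degrees, in [0, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 == 0.0:
        raise GeometryError("degenerate dihedral: coincident central atoms")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(abs(np.degrees(np.arctan2(y, x))))


def ring_geometry(coords) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit best-fit-plane normal of a set of ring atoms.

    The normal is the eigenvector of the smallest covariance eigenvalue
    (total-least-squares plane).  Raises :class:`GeometryError` for fewer
    than three atoms or a collinear arrangement.
    """
    xyz = np.asarray(coords, float)
    if xyz.ndim != 2 or xyz.shape[0] < 3 or xyz.shape[1] != 3:
        raise GeometryError("ring geometry needs >= 3 points in 3-D")
    centroid = xyz.mean(axis=0)
    centered = xyz - centroid
    # singular values sorted descending; right-singular vector of the
    # smallest one is the plane normal
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise GeometryError("collinear ring atoms: plane is undefined")
    normal = vt[2]
    normal = normal / np.linalg.norm(normal)
    return centroid, normal


def plane_offset(centroid_a, normal_a, centroid_b) -> float:
    """In-plane offset of centroid_b projected onto the plane of ring a."""
    d = np.asarray(centroid_b, float) - np.asarray(centroid_a, float)
    normal_a = np.asarray(normal_a, float)
    along = np.dot(d, normal_a)
    return float(np.linalg.norm(d - along * normal_a))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a gaussian matrix, det fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
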