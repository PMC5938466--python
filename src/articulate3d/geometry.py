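"""Rigid-motion primitives on 3D landmark configurations.

This module is the mathematical core of the package: translation of a
point set so a chosen landmark sits at a chosen origin, unit plane
normals, inter-vector angles, axis–angle (Rodrigues) rotation matrices,
the alignment rotation that carries one vector onto another within their
common plane, and the in-axis "constraint" rotation that spins an
already-aligned structure about its main axis until a designated
landmark lies in the reference plane.

Conventions
-----------
* Points and vectors are ``numpy`` arrays of shape ``(3,)``; a point set
  is an array of shape ``(n_landmarks, 3)``.  All functions are pure and
  never modify their inputs.
* Landmark indices in this module are **0-based** (the user-facing
  articulation API and the CLI are 1-based, matching morphometric
  practice).
* Angles are in radians throughout this module; the only degree-valued
  entry point is :func:`degrees_to_vector`, which mirrors the public
  API's degree convention.
* Every rotation matrix produced here is proper (orthonormal with
  determinant +1): these functions can never introduce a reflection,
  which is what makes them safe for shape data.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "UNIT_TOL",
    "PARALLEL_TOL",
    "translate_points",
    "plane_normal",
    "vector_angle",
    "axis_angle_rotation",
    "align_rotation",
    "rotate_points",
    "in_axis_correction",
    "degrees_to_vector",
    "is_rotation_matrix",
]

#: tolerance for "this axis must be a unit vector"
UNIT_TOL = 1e-9
#: |u x v| / (|u||v|) below this counts as parallel (sine of the angle)
PARALLEL_TOL = 1e-12

_X = np.array([1.0, 0.0, 0.0])


def _vec3(v, name: str = "vector") -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must have shape (3,), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} has non-finite components: {arr}")
    return arr


def _point_set(points) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(
            f"point set must have shape (n_landmarks, 3), got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("point set contains non-finite coordinates")
    return arr


def translate_points(points, base: int, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Translate a point set so landmark ``base`` lands exactly on ``origin``.

    The same displacement is applied to every landmark, so all pairwise
    distances (and handedness) are unchanged.  With the default origin
    this is the standard "move the articulation point to (0, 0, 0)" step
    that precedes any rotation.

    Parameters
    ----------
    points : array-like, shape (n, 3)
    base : int
        0-based index of the landmark to place on ``origin``.
    origin : array-like, shape (3,), default (0, 0, 0)
    """
    pts = _point_set(points)
    n = pts.shape[0]
    if not -n <= base < n:
        raise IndexError(f"base landmark index {base} out of range for {n} landmarks")
    org = _vec3(origin, "origin")
    return pts - (pts[base] - org)


def plane_normal(u, v) -> np.ndarray:
    """Unit normal ``(u x v) / |u x v|`` of the plane spanned by u and v.

    The orientation follows the cross-product order of the arguments.
    Raises :class:`DegenerateGeometryError` when u and v are (anti)parallel
    or zero, since the plane is then undefined.
    """
    uu = _vec3(u, "u")
    vv = _vec3(v, "v")
    nu = np.linalg.norm(uu)
    nv = np.linalg.norm(vv)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("plane_normal requires nonzero vectors")
    c = np.cross(uu, vv)
    s = np.linalg.norm(c)
    if s / (nu * nv) < PARALLEL_TOL:
        raise DegenerateGeometryError(
            "plane normal undefined: vectors are parallel or antiparallel"
        )
    return c / s


def vector_angle(u, v) -> float:
    """Angle between two nonzero vectors, in radians, in [0, pi].

    Computed as ``arccos(u.v / (|u||v|))`` with the cosine clamped to
    [-1, 1] to absorb floating-point drift.  Symmetric in its arguments
    and invariant to rescaling either one.
    """
    uu = _vec3(u, "u")
    vv = _vec3(v, "v")
    nu = np.linalg.norm(uu)
    nv = np.linalg.norm(vv)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("vector_angle requires nonzero vectors")
    cosang = float(np.dot(uu, vv) / (nu * nv))
    return math.acos(min(1.0, max(-1.0, cosang)))


def axis_angle_rotation(w, theta: float) -> np.ndarray:
    """Rodrigues rotation matrix for a right-handed rotation by ``theta``
    radians about the **unit** axis ``w``.

    The axis must already be unit-norm (within ``UNIT_TOL``); it is a
    caller error to pass an unnormalized axis, and it is *not* silently
    normalized.  The returned matrix ``R`` satisfies ``R @ w == w``,
    ``R.T @ R == I`` and ``det(R) == +1``.
    """
    ww = _vec3(w, "axis")
    if abs(np.linalg.norm(ww) - 1.0) > UNIT_TOL:
        raise ValueError(
            f"rotation axis must be unit norm (|w| = {np.linalg.norm(ww):.12g})"
        )
    if not math.isfinite(theta):
        raise ValueError("rotation angle must be finite")
    w1, w2, w3 = ww
    c = math.cos(theta)
    s = math.sin(theta)
    t = 1.0 - c
    return np.array(
        [
            [c + w1 * w1 * t, w1 * w2 * t - w3 * s, w1 * w3 * t + w2 * s],
            [w2 * w1 * t + w3 * s, c + w2 * w2 * t, w2 * w3 * t - w1 * s],
            [w3 * w1 * t - w2 * s, w3 * w2 * t + w1 * s, c + w3 * w3 * t],
        ]
    )


def _perpendicular_axis(u: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to u: the canonical basis
    vector most orthogonal to u, projected onto u's orthogonal complement
    and normalized."""
    uhat = u / np.linalg.norm(u)
    dots = np.abs(np.eye(3) @ uhat)
    e = np.eye(3)[int(np.argmin(dots))]
    perp = e - np.dot(e, uhat) * uhat
    return perp / np.linalg.norm(perp)


def align_rotation(u, v) -> np.ndarray:
    """Proper rotation carrying ``u/|u|`` onto ``v/|v|`` within their
    common plane.

    The rotation axis is the unit plane normal of (u, v) and the angle is
    their inter-vector angle, so this is the minimal-angle rotation
    between the two directions.  Degenerate directions are handled
    deterministically:

    * parallel (sine of the angle below ``PARALLEL_TOL``): identity;
    * antiparallel: rotation by pi about a deterministic perpendicular
      axis (the canonical basis vector most orthogonal to u, projected
      perpendicular to u).
    """
    uu = _vec3(u, "u")
    vv = _vec3(v, "v")
    nu = np.linalg.norm(uu)
    nv = np.linalg.norm(vv)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("align_rotation requires nonzero vectors")
    sine = np.linalg.norm(np.cross(uu, vv)) / (nu * nv)
    if sine < PARALLEL_TOL:
        if np.dot(uu, vv) > 0.0:
            return np.eye(3)
        return axis_angle_rotation(_perpendicular_axis(uu), math.pi)
    return axis_angle_rotation(plane_normal(uu, vv), vector_angle(uu, vv))


def rotate_points(R, points) -> np.ndarray:
    """Apply the rotation matrix ``R`` to every point of a point set.

    The origin is a fixed point of the map; pairwise distances and
    handedness are preserved for any proper rotation ``R``.
    """
    RR = np.asarray(R, dtype=float)
    if RR.shape != (3, 3) or not np.all(np.isfinite(RR)):
        raise ValueError("R must be a finite 3x3 matrix")
    pts = _point_set(points)
    return pts @ RR.T


def is_rotation_matrix(R, tol: float = UNIT_TOL) -> bool:
    """True when R is orthonormal with determinant +1 within ``tol``."""
    RR = np.asarray(R, dtype=float)
    if RR.shape != (3, 3):
        return False
    return bool(
        np.all(np.abs(RR.T @ RR - np.eye(3)) <= tol)
        and abs(np.linalg.det(RR) - 1.0) <= tol
    )


def _in_axis_frame(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal frame (e1, e2) of the plane perpendicular to unit a,
    with e2 = a x e1, chosen deterministically from the first canonical
    basis vector not nearly parallel to a (order x, y, z).

    For a = (0, 1, 0) this gives e1 = (1, 0, 0), e2 = -(0, 0, 1), so the
    correction angle reduces to the quadrant-aware arctan of (z, x): the
    constraint landmark ends at zero third coordinate and positive first
    coordinate.
    """
    for e in np.eye(3):
        if abs(np.dot(e, a)) < 0.9:
            e1 = e - np.dot(e, a) * a
            e1 /= np.linalg.norm(e1)
            return e1, np.cross(a, e1)
    raise AssertionError("unreachable: some basis vector is non-parallel")


def in_axis_correction(points, constraint_index: int, axis) -> np.ndarray:
    """Rotate a point set about ``axis`` so the constraint landmark lies
    in the reference plane containing the axis.

    The structure is assumed to be already aligned so its main axis
    coincides with ``axis`` (a unit vector); the rotation then only
    spins the structure about that axis, leaving the alignment intact.
    After correction the constraint landmark's out-of-plane coordinate
    is 0 and its in-plane off-axis coordinate is positive, which also
    resolves the mirroring ambiguity of a two-landmark axis.

    The correction angle is the quadrant-aware arctangent of the
    constraint landmark's two off-axis coordinates, so the constraint is
    satisfied in every quadrant.

    Raises
    ------
    DegenerateGeometryError
        If the constraint landmark lies on the axis (off-axis component
        zero): the in-axis rotation is then undefined.
    """
    pts = _point_set(points)
    a = _vec3(axis, "axis")
    if abs(np.linalg.norm(a) - 1.0) > UNIT_TOL:
        raise ValueError("axis must be a unit vector")
    n = pts.shape[0]
    if not -n <= constraint_index < n:
        raise IndexError(
            f"constraint landmark index {constraint_index} out of range for {n} landmarks"
        )
    r = pts[constraint_index]
    e1, e2 = _in_axis_frame(a)
    c1 = float(np.dot(r, e1))
    c2 = float(np.dot(r, e2))
    if math.hypot(c1, c2) <= 1e-12 * max(1.0, float(np.linalg.norm(r))):
        raise DegenerateGeometryError(
            "constraint landmark lies on the rotation axis; in-axis rotation undefined"
        )
    phi = -math.atan2(c2, c1)
    return rotate_points(axis_angle_rotation(a, phi), pts)


def degrees_to_vector(angle_deg: float) -> np.ndarray:
    """Unit vector in the XY-plane forming ``angle_deg`` degrees with (1, 0, 0).

    ``degrees_to_vector(90)`` is exactly (0, 1, 0): this is the target
    direction for the second structure's axis when a 90-degree
    inter-structure angle is requested.  Valid input range is 0 to 360
    degrees inclusive.
    """
    if not math.isfinite(angle_deg) or not 0.0 <= angle_deg <= 360.0:
        raise ValueError(
            f"angle must be between 0 and 360 degrees, got {angle_deg!r}"
        )
    th = math.radians(angle_deg)
    return np.array([math.cos(th), math.sin(th), 0.0])
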