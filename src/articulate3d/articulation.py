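"""Standardization of articulated two-structure landmark configurations.

Two procedures are provided, matching the two kinds of joints that occur
in practice:

* **single-point articulation** (e.g. humerus + radioulna meeting at the
  elbow): three role landmarks per structure — articulation/base point,
  axis end point, and an orient landmark that resolves the mirroring
  ambiguity of a two-landmark axis;
* **double-point articulation** (e.g. skull + detached mandible with two
  jaw-joint hinges): four role landmarks per structure — the fourth
  closes a tetrahedron whose signed volume is used as a handedness
  (chirality) check, since a reflected specimen cannot be repaired by
  any rigid rotation.

Both procedures place structure 1's base-to-end axis along the reference
axis (1, 0, 0) with its orient landmark in the XY-plane at positive y,
and structure 2's axis along the unit vector at the requested
inter-structure angle within the XY-plane.  Everything applied is a
proper rigid rotation about the shared origin, so per-structure shape
(all pairwise distances and handedness) is untouched — only the
articulation-induced pose varies, and it is removed.

All landmark role indices here are **1-based**, following morphometric
convention ("the 10th landmark").
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .datasets import (
    JoinedDataset,
    LandmarkArray,
    StructurePair,
    join_arrays,
    match_datasets,
)
from .errors import DegenerateGeometryError, ReflectionError

__all__ = [
    "ArticulationSpec",
    "QualityFlag",
    "QualityReport",
    "simple_rotation",
    "double_rotation",
    "mirror_correct",
    "check_landmark_quality",
    "offset_structure",
    "measure_inter_axis_angles_deg",
]

_X = np.array([1.0, 0.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])

#: role pair closer than this fraction of centroid size counts as coincident
COINCIDENT_REL_TOL = 1e-6
#: sine of the angle at the base below this flags a near-collinear role triple
COLLINEAR_SINE_TOL = 0.01


@dataclass(frozen=True)
class ArticulationSpec:
    """Role-landmark indices for both structures plus the target angle.

    ``roles_1`` / ``roles_2`` are 1-based index tuples: ``(base, end,
    orient)`` for a single-point articulation, ``(base, end, orient,
    chirality)`` for a double-point articulation.  The base landmark is
    the articulation point and must be translated to the origin before
    rotating.  ``target_angle_deg`` is the desired angle between the two
    standardized structure axes, 0–360 degrees.
    """

    roles_1: tuple[int, ...]
    roles_2: tuple[int, ...]
    target_angle_deg: float

    def __post_init__(self) -> None:
        for name, roles in (("roles_1", self.roles_1), ("roles_2", self.roles_2)):
            roles = tuple(int(r) for r in roles)
            object.__setattr__(self, name, roles)
            if len(roles) not in (3, 4):
                raise ValueError(
                    f"{name} must have 3 (single) or 4 (double) role indices, "
                    f"got {len(roles)}"
                )
            if any(r < 1 for r in roles):
                raise ValueError(f"{name} indices are 1-based and must be >= 1")
            if len(set(roles)) != len(roles):
                raise ValueError(f"{name} role indices must be distinct: {roles}")
        if len(self.roles_1) != len(self.roles_2):
            raise ValueError("both structures must use the same articulation kind")
        if not 0.0 <= float(self.target_angle_deg) <= 360.0:
            raise ValueError(
                f"target angle must be in [0, 360] degrees, got {self.target_angle_deg}"
            )

    @property
    def joint_type(self) -> str:
        return "single" if len(self.roles_1) == 3 else "double"


@dataclass(frozen=True)
class QualityFlag:
    specimen_id: str
    structure: int  # 1 or 2
    kind: str  # "coincident_axis_pair" | "collinear_roles"
    detail: str


@dataclass
class QualityReport:
    """Result of :func:`check_landmark_quality`.

    ``flags`` lists genuine problems (coincident axis pairs,
    near-collinear role triples).  ``shared_coordinate_deviation`` is
    informational only: for each (specimen, structure) it records how far
    the orient landmark is from sharing a coordinate with the axis end
    landmark — guidance for landmark choice, never an error.
    """

    flags: list[QualityFlag] = field(default_factory=list)
    shared_coordinate_deviation: dict[tuple[str, int], float] = field(
        default_factory=dict
    )

    @property
    def is_empty(self) -> bool:
        return not self.flags

    def summary(self) -> str:
        if self.is_empty:
            return "no landmark-quality problems detected"
        lines = [
            f"specimen {f.specimen_id!r}, structure {f.structure}: "
            f"{f.kind} ({f.detail})"
            for f in self.flags
        ]
        return "landmark choice not optimal:\n" + "\n".join(lines)


def _as_pair(pair) -> StructurePair:
    if isinstance(pair, StructurePair):
        return pair
    if isinstance(pair, (tuple, list)) and len(pair) == 2:
        d1, d2 = pair
        if d1.specimen_ids == d2.specimen_ids:
            return StructurePair(d1, d2)
        return match_datasets(d1, d2)
    raise TypeError(
        "expected a StructurePair or a (LandmarkArray, LandmarkArray) pair"
    )


def _check_roles(data: LandmarkArray, roles: tuple[int, ...], structure: int) -> None:
    for r in roles:
        if not 1 <= r <= data.landmark_count:
            raise IndexError(
                f"structure {structure}: role landmark {r} out of range "
                f"1..{data.landmark_count}"
            )


def _standardize(coords: np.ndarray, roles: tuple[int, ...],
                 specimen_id: str, structure: int) -> np.ndarray:
    """Place one translated structure in the reference pose: base-to-end
    axis along +X, orient landmark in the XY-plane at positive y."""
    base, end, orient = (r - 1 for r in roles[:3])
    scale = max(1.0, float(np.max(np.abs(coords))))
    if np.linalg.norm(coords[base]) > 1e-7 * scale:
        raise ValueError(
            f"specimen {specimen_id!r}, structure {structure}: articulation "
            f"landmark {roles[0]} is not at the origin; translate the "
            "structure first (datasets.translate)"
        )
    axis_vec = coords[end] - coords[base]
    if np.linalg.norm(axis_vec) <= 1e-12 * scale:
        raise DegenerateGeometryError(
            f"specimen {specimen_id!r}, structure {structure}: axis landmarks "
            f"{roles[0]} and {roles[1]} coincide"
        )
    out = geometry.rotate_points(geometry.align_rotation(axis_vec, _X), coords)
    try:
        out = geometry.in_axis_correction(out, orient, _X)
    except DegenerateGeometryError as err:
        raise DegenerateGeometryError(
            f"specimen {specimen_id!r}, structure {structure}: {err}"
        ) from None
    return out


def _warn_quality(pair: StructurePair, spec: ArticulationSpec) -> QualityReport:
    report = check_landmark_quality(pair, spec)
    if not report.is_empty:
        warnings.warn(report.summary(), stacklevel=3)
    return report


def _rotate_pair(pair, spec: ArticulationSpec,
                 expected_roles: int) -> tuple[StructurePair, np.ndarray, np.ndarray]:
    """Shared core of simple_rotation / double_rotation: standardize both
    structures per specimen, then place structure 2 at the target angle."""
    pair = _as_pair(pair)
    if len(spec.roles_1) != expected_roles:
        kind = "simple_rotation" if expected_roles == 3 else "double_rotation"
        raise ValueError(
            f"{kind} needs {expected_roles} role landmarks per structure, "
            f"got {len(spec.roles_1)}"
        )
    _check_roles(pair.data_1, spec.roles_1, 1)
    _check_roles(pair.data_2, spec.roles_2, 2)
    _warn_quality(pair, spec)
    if expected_roles == 4:
        _check_reflection(pair.data_1, spec.roles_1, 1)
        _check_reflection(pair.data_2, spec.roles_2, 2)

    r_target = geometry.axis_angle_rotation(
        _Z, math.radians(float(spec.target_angle_deg))
    )
    out1 = np.empty_like(pair.data_1.coords)
    out2 = np.empty_like(pair.data_2.coords)
    for i, sid in enumerate(pair.specimen_ids):
        out1[:, :, i] = _standardize(pair.data_1.coords[:, :, i], spec.roles_1, sid, 1)
        std2 = _standardize(pair.data_2.coords[:, :, i], spec.roles_2, sid, 2)
        out2[:, :, i] = geometry.rotate_points(r_target, std2)
    return pair, out1, out2


def simple_rotation(pair, spec: ArticulationSpec) -> JoinedDataset:
    """Standardize a single-point articulation and join the structures.

    Both structures must already be translated so their articulation
    (first role) landmark is at the origin.  Per specimen, structure 1
    is rotated so its base-to-end axis lies along (1, 0, 0) and its
    orient landmark sits in the XY-plane at positive y (the mirroring
    fix); structure 2 is standardized the same way and then rotated
    within the XY-plane so the angle between the two axes equals
    ``spec.target_angle_deg``.  Specimens present in only one input are
    dropped with a warning.

    Returns the per-specimen join of the two rotated structures, with
    provenance tags.
    """
    pair, out1, out2 = _rotate_pair(pair, spec, expected_roles=3)
    return join_arrays(
        LandmarkArray(out1, list(pair.specimen_ids)),
        LandmarkArray(out2, list(pair.specimen_ids)),
    )


def double_rotation(pair, spec: ArticulationSpec) -> tuple[LandmarkArray, LandmarkArray]:
    """Standardize a double-point articulation; return the two rotated arrays.

    Requires four role landmarks per structure: per structure the hinge
    axis (roles 1–2) is aligned with the reference axis, an in-axis
    rotation places role 3 in the reference plane (removing torsion),
    and role 4 closes the tetrahedron used for the chirality check — a
    specimen whose role quadruple has handedness inconsistent with the
    rest of its structure raises :class:`ReflectionError` rather than
    being silently "fixed", because no rigid rotation can undo a
    reflection.  Structure 2 is additionally rotated within the XY-plane
    to the target inter-structure angle.

    The two arrays are returned separately; join them with
    :func:`articulate3d.datasets.join_arrays` (optionally after
    :func:`offset_structure`).
    """
    pair, out1, out2 = _rotate_pair(pair, spec, expected_roles=4)
    return (
        LandmarkArray(out1, list(pair.specimen_ids)),
        LandmarkArray(out2, list(pair.specimen_ids)),
    )


def _signed_volumes(data: LandmarkArray, roles: tuple[int, ...]) -> np.ndarray:
    a, b, c, d = (r - 1 for r in roles)
    p = data.coords
    m = np.stack(
        [p[b] - p[a], p[c] - p[a], p[d] - p[a]], axis=0
    )  # (3, 3, n)
    return np.array([np.linalg.det(m[:, :, i]) for i in range(data.specimen_count)])


def _check_reflection(data: LandmarkArray, roles: tuple[int, ...],
                      structure: int) -> None:
    """Raise ReflectionError when the role-quadruple signed volume changes
    sign across specimens (a reflected specimen among unreflected ones)."""
    vols = _signed_volumes(data, roles)
    scale = np.maximum(np.max(np.abs(data.coords), axis=(0, 1)), 1.0) ** 3
    valid = np.abs(vols) > 1e-12 * scale
    signs = np.sign(vols[valid])
    if signs.size < 2 or np.all(signs == signs[0]):
        return
    majority = 1.0 if np.sum(signs > 0) >= np.sum(signs < 0) else -1.0
    ids = np.asarray(data.specimen_ids)[valid][signs != majority]
    raise ReflectionError(
        f"structure {structure}: specimens {list(ids)} have handedness "
        "opposite to the rest (reflected input); a rigid rotation cannot "
        "undo a reflection"
    )


def mirror_correct(points, axis, orient_index: int) -> np.ndarray:
    """In-axis rotation fixing the mirroring orientation of an
    axis-aligned point set.

    After correction the orient landmark (0-based index) has zero
    out-of-plane coordinate and strictly positive in-plane off-axis
    coordinate; handedness is unchanged because only a rotation about
    ``axis`` is applied.  This is the resolution of the two-landmark
    axis ambiguity: without the orient landmark the structure could be
    placed in either of two mirror-image-looking poses.
    """
    out = geometry.in_axis_correction(points, orient_index, axis)
    return out


def check_landmark_quality(pair, spec: ArticulationSpec) -> QualityReport:
    """Scan role landmarks for configurations that make rotation unstable.

    Flags, per specimen and structure: an axis pair closer than
    ``COINCIDENT_REL_TOL`` x centroid size, and a base/end/orient triple
    whose angle at the base has sine below ``COLLINEAR_SINE_TOL``
    (near-collinear, so the in-axis correction is ill-conditioned).
    Reporting only — never blocks execution.
    """
    pair = _as_pair(pair)
    report = QualityReport()
    for structure, data, roles in (
        (1, pair.data_1, spec.roles_1),
        (2, pair.data_2, spec.roles_2),
    ):
        _check_roles(data, roles, structure)
        base, end, orient = (r - 1 for r in roles[:3])
        for i, sid in enumerate(pair.specimen_ids):
            pts = data.coords[:, :, i]
            centroid = pts.mean(axis=0)
            csize = float(np.sqrt(np.sum((pts - centroid) ** 2)))
            csize = max(csize, np.finfo(float).tiny)
            axis_vec = pts[end] - pts[base]
            axis_len = float(np.linalg.norm(axis_vec))
            if axis_len < COINCIDENT_REL_TOL * csize:
                report.flags.append(QualityFlag(
                    sid, structure, "coincident_axis_pair",
                    f"axis landmarks {roles[0]} and {roles[1]} are "
                    f"{axis_len:.3g} apart (centroid size {csize:.3g})",
                ))
                continue
            orient_vec = pts[orient] - pts[base]
            orient_len = float(np.linalg.norm(orient_vec))
            if orient_len < COINCIDENT_REL_TOL * csize:
                report.flags.append(QualityFlag(
                    sid, structure, "collinear_roles",
                    f"orient landmark {roles[2]} coincides with base {roles[0]}",
                ))
                continue
            sine = float(
                np.linalg.norm(np.cross(axis_vec, orient_vec))
                / (axis_len * orient_len)
            )
            if sine < COLLINEAR_SINE_TOL:
                report.flags.append(QualityFlag(
                    sid, structure, "collinear_roles",
                    f"role landmarks {roles[0]}, {roles[1]}, {roles[2]} are "
                    f"near-collinear (sine {sine:.3g})",
                ))
            dev = float(np.min(np.abs(pts[orient] - pts[end])))
            report.shared_coordinate_deviation[(sid, structure)] = dev
    return report


def offset_structure(data: LandmarkArray, anchor: int, offset) -> LandmarkArray:
    """Rigidly displace a whole structure by ``offset``.

    Used after rotation to separate the two structures when they should
    not be drawn or analyzed in contact.  ``anchor`` (1-based) names the
    landmark the offset is expressed relative to; since the displacement
    is rigid, every landmark — anchor included — moves by exactly
    ``offset`` and all inter-landmark geometry is unchanged.
    """
    if not 1 <= anchor <= data.landmark_count:
        raise IndexError(f"anchor {anchor} out of range 1..{data.landmark_count}")
    off = np.asarray(offset, dtype=float)
    if off.shape != (3,) or not np.all(np.isfinite(off)):
        raise ValueError("offset must be a finite 3-vector")
    return LandmarkArray(data.coords + off[None, :, None], list(data.specimen_ids))


def measure_inter_axis_angles_deg(d1: LandmarkArray, d2: LandmarkArray,
                                  spec: ArticulationSpec) -> np.ndarray:
    """Per-specimen angle (degrees, in [0, 180]) between the two
    structures' base-to-end role axes — the quantity the target angle
    controls."""
    pair = _as_pair((d1, d2))
    _check_roles(pair.data_1, spec.roles_1, 1)
    _check_roles(pair.data_2, spec.roles_2, 2)
    b1, e1 = spec.roles_1[0] - 1, spec.roles_1[1] - 1
    b2, e2 = spec.roles_2[0] - 1, spec.roles_2[1] - 1
    out = np.empty(pair.specimen_count)
    for i in range(pair.specimen_count):
        v1 = pair.data_1.coords[e1, :, i] - pair.data_1.coords[b1, :, i]
        v2 = pair.data_2.coords[e2, :, i] - pair.data_2.coords[b2, :, i]
        out[i] = math.degrees(geometry.vector_angle(v1, v2))
    return out
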