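"""Synthetic articulated specimens with known ground truth.

The generator emulates the experimental situation the standardization
procedures exist for: every specimen shares one template shape per
structure, but each structure has been independently (and randomly)
translated and rotated — the joint angle varies from specimen to
specimen — exactly the articulation-induced nuisance variation the
rotation pipeline is meant to remove.  Because the applied rigid motions
are recorded, pose invariance and ground-truth recovery are directly
testable: standardizing any specimen must reproduce the template
configuration, whatever motion was applied.

Templates are generated in the standardized reference pose (axis along
+X, orient landmark in the XY-plane at positive y), so the expected
standardized output at target angle theta is simply ``template_1`` and
``R_z(theta) @ template_2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import geometry
from .articulation import ArticulationSpec
from .datasets import LandmarkArray, StructurePair

__all__ = [
    "SyntheticSpecimenSet",
    "make_articulated_pair",
    "make_degenerate_cases",
]


@dataclass
class SyntheticSpecimenSet:
    """An articulated two-structure sample with recorded ground truth.

    ``data_1`` / ``data_2`` hold the observed (randomly posed)
    coordinates; ``template_1`` / ``template_2`` the shared shapes in
    standardized pose; the rotation/translation actually applied to each
    structure of each specimen is kept for pose-invariance tests.
    """

    data_1: LandmarkArray
    data_2: LandmarkArray
    template_1: np.ndarray  # (p1, 3), standardized pose
    template_2: np.ndarray  # (p2, 3), standardized pose
    roles_1: tuple[int, ...]
    roles_2: tuple[int, ...]
    joint_type: str
    rotations_1: np.ndarray  # (n, 3, 3)
    rotations_2: np.ndarray
    translations_1: np.ndarray  # (n, 3)
    translations_2: np.ndarray
    joint_angles_deg: np.ndarray  # (n,)
    noise_sd: float
    seed: int

    @property
    def pair(self) -> StructurePair:
        return StructurePair(self.data_1, self.data_2)

    def articulation_spec(self, target_angle_deg: float) -> ArticulationSpec:
        return ArticulationSpec(self.roles_1, self.roles_2, target_angle_deg)

    def standardized_truth(
        self, target_angle_deg: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Expected standardized coordinates of every specimen at the
        given target angle: (template_1, R_z(theta) @ template_2)."""
        rz = geometry.axis_angle_rotation(
            np.array([0.0, 0.0, 1.0]), math.radians(target_angle_deg)
        )
        return self.template_1.copy(), self.template_2 @ rz.T


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Proper rotation from a uniform random unit axis and uniform angle,
    built with the package's own Rodrigues primitive (the independent
    quaternion oracle in the test suite keeps this honest)."""
    while True:
        axis = rng.normal(size=3)
        n = np.linalg.norm(axis)
        if n > 1e-6:
            break
    return geometry.axis_angle_rotation(axis / n, rng.uniform(0.0, 2.0 * math.pi))


def _template(rng: np.random.Generator, n_landmarks: int, n_roles: int,
              axis_length: float, orient: np.ndarray,
              chir: np.ndarray) -> np.ndarray:
    """Template in standardized pose with well-separated role landmarks
    at indices 0..n_roles-1; remaining landmarks are random but fixed."""
    pts = np.zeros((n_landmarks, 3))
    pts[0] = 0.0  # base / articulation point
    pts[1] = (axis_length, 0.0, 0.0)  # axis end
    pts[2] = orient  # orient landmark, XY-plane, y > 0
    if n_roles == 4:
        pts[3] = chir  # off-plane: closes the chirality tetrahedron
    pts[n_roles:] = rng.uniform(-1.0, 2.0, size=(n_landmarks - n_roles, 3))
    return pts


def make_articulated_pair(
    n_specimens: int = 20,
    n_landmarks: tuple[int, int] = (8, 10),
    joint_type: str = "single",
    angle_range_deg: tuple[float, float] = (20.0, 160.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticSpecimenSet:
    """Generate an articulated two-structure specimen set.

    Per specimen: a joint angle is drawn uniformly from
    ``angle_range_deg``, structure 2's template is posed at that angle,
    and each structure then receives an independent uniform random
    proper rotation and a translation drawn uniformly from (-5, 5) per
    coordinate.  Optional isotropic Gaussian noise of standard deviation
    ``noise_sd`` is added to non-role landmarks only, so role geometry
    (and hence degeneracy) stays controlled.

    Fully deterministic under ``seed``.
    """
    if joint_type not in ("single", "double"):
        raise ValueError(f"joint_type must be 'single' or 'double', got {joint_type!r}")
    p1, p2 = (int(p) for p in n_landmarks)
    if p1 < 4 or p2 < 4:
        raise ValueError("each structure needs at least 4 landmarks")
    lo, hi = (float(a) for a in angle_range_deg)
    if not (0.0 <= lo <= hi <= 360.0):
        raise ValueError("angle_range_deg must satisfy 0 <= lo <= hi <= 360")
    if noise_sd < 0.0:
        raise ValueError("noise_sd must be >= 0")
    if n_specimens < 1:
        raise ValueError("need at least one specimen")

    n_roles = 3 if joint_type == "single" else 4
    roles = tuple(range(1, n_roles + 1))
    rng = np.random.default_rng(seed)

    template_1 = _template(rng, p1, n_roles, axis_length=2.0,
                           orient=np.array([0.6, 0.9, 0.0]),
                           chir=np.array([0.8, 0.4, 0.7]))
    template_2 = _template(rng, p2, n_roles, axis_length=1.6,
                           orient=np.array([0.5, 0.7, 0.0]),
                           chir=np.array([0.6, 0.3, 0.9]))

    angles = rng.uniform(lo, hi, size=n_specimens)
    z = np.array([0.0, 0.0, 1.0])
    coords_1 = np.empty((p1, 3, n_specimens))
    coords_2 = np.empty((p2, 3, n_specimens))
    rot_1 = np.empty((n_specimens, 3, 3))
    rot_2 = np.empty((n_specimens, 3, 3))
    tra_1 = np.empty((n_specimens, 3))
    tra_2 = np.empty((n_specimens, 3))
    for i in range(n_specimens):
        posed_2 = template_2 @ geometry.axis_angle_rotation(
            z, math.radians(angles[i])
        ).T
        for (tmpl, coords, rots, tras) in (
            (template_1, coords_1, rot_1, tra_1),
            (posed_2, coords_2, rot_2, tra_2),
        ):
            r = _random_rotation(rng)
            t = rng.uniform(-5.0, 5.0, size=3)
            obs = tmpl @ r.T + t
            if noise_sd > 0.0:
                obs[n_roles:] += rng.normal(0.0, noise_sd,
                                            size=obs[n_roles:].shape)
            coords[:, :, i] = obs
            rots[i] = r
            tras[i] = t

    ids = [f"spec_{i + 1:03d}" for i in range(n_specimens)]
    return SyntheticSpecimenSet(
        data_1=LandmarkArray(coords_1, ids),
        data_2=LandmarkArray(coords_2, list(ids)),
        template_1=template_1,
        template_2=template_2,
        roles_1=roles,
        roles_2=roles,
        joint_type=joint_type,
        rotations_1=rot_1,
        rotations_2=rot_2,
        translations_1=tra_1,
        translations_2=tra_2,
        joint_angles_deg=angles,
        noise_sd=float(noise_sd),
        seed=int(seed),
    )


def make_degenerate_cases(seed: int = 0) -> dict[str, StructurePair]:
    """Labelled pathological fixtures, each triggering one documented
    error or warning path.

    Keys
    ----
    ``collinear_roles``
        Structure 1's orient landmark lies exactly on the base–end
        line: flagged by :func:`check_landmark_quality`, and the in-axis
        correction raises a degenerate-geometry error.
    ``coincident_axis_pair``
        Structure 1's two axis landmarks coincide: axis undefined.
    ``reflected``
        Two specimens, the second a mirror image of the first: the
        double-point chirality check raises a reflection error.
    ``orient_on_axis``
        Orient landmark on the axis beyond the end landmark — same
        degenerate in-axis geometry reached through a well-separated
        axis pair.

    All structures are pre-translated (base landmark at the origin) so
    they can be fed straight into the rotation procedures.
    """
    rng = np.random.default_rng(seed)
    good = _template(rng, 5, 4, axis_length=1.5,
                     orient=np.array([0.4, 0.8, 0.0]),
                     chir=np.array([0.5, 0.3, 0.6]))

    def pair_from(bad_specimens: list[np.ndarray]) -> StructurePair:
        ids = [f"d{i + 1}" for i in range(len(bad_specimens))]
        c1 = np.stack(bad_specimens, axis=2)
        c2 = np.stack([good] * len(bad_specimens), axis=2)
        return StructurePair(LandmarkArray(c1, ids), LandmarkArray(c2, list(ids)))

    collinear = good.copy()
    collinear[2] = 0.5 * collinear[1]  # orient exactly on the base-end line

    coincident = good.copy()
    coincident[1] = coincident[0]  # axis landmarks coincide

    reflected = good.copy()
    reflected[:, 2] *= -1.0  # mirror in the XY-plane

    on_axis = good.copy()
    on_axis[2] = 2.0 * on_axis[1]  # orient past the end landmark, on axis

    return {
        "collinear_roles": pair_from([collinear]),
        "coincident_axis_pair": pair_from([coincident]),
        "reflected": pair_from([good, reflected]),
        "orient_on_axis": pair_from([on_axis]),
    }
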