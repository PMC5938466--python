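# Methods

## Model and assumptions

`articulate3d` treats each specimen as two rigid sub-structures
connected (or nearly connected) at a joint. The observed coordinates of
each structure are assumed to be a proper rigid motion (rotation +
translation, no scaling, no reflection) of a shape of interest; the
joint contributes an arbitrary, biologically uninformative relative
pose. Standardization removes that pose by moving each structure into a
canonical reference frame defined entirely by user-chosen *role
landmarks*:

* structure 1: base-to-end axis on the +X half-axis, orient landmark in
  the XY-plane with positive y;
* structure 2: same construction, then rotated within the XY-plane so
  its axis points along `(cos θ_T, sin θ_T, 0)` for the target angle
  θ_T.

Because the reference frame is built from landmarks of the structure
itself, the result is invariant under any rigid motion of the input:
that is the method's entire purpose, and the test suite verifies it
directly (50 random rigid motions per procedure, maximum coordinate
deviation bounded by 1e-6).

Semilandmarks are handled like landmarks; if they are slid or
resampled, that must happen before standardization so they are
comparable across specimens. Generalized Procrustes analysis, size
removal and all downstream statistics are deliberately out of scope —
the output TPS file is meant to be fed to standard GM software.

## Procedure details

**Rotation primitives.** Alignment of a vector u onto v uses the
minimal rotation in their common plane: axis `(u x v)/|u x v|`, angle
`arccos(u.v/|u||v|)` (cosine clamped to [-1, 1]), composed through the
explicit Rodrigues axis–angle matrix. Axes passed to the Rodrigues
constructor must be unit vectors within 1e-9 — unnormalized axes are
rejected, never silently normalized, so an upstream normalization bug
cannot hide.

**Degenerate directions.** If u and v are parallel (sine below 1e-12)
the alignment is the identity. If they are antiparallel, the plane
normal is undefined; the axis is then chosen deterministically as the
canonical basis vector most orthogonal to u, projected onto u's
orthogonal complement and normalized, with a rotation of π. Any
perpendicular axis would be correct; determinism makes runs
reproducible.

**In-axis constraint.** After axis alignment the structure can still
spin freely about its axis. The correction angle is the two-argument
(quadrant-aware) arctangent of the orient landmark's two off-axis
coordinates; a single-argument arctangent would satisfy the planarity
constraint in only half the quadrants and could leave the structure in
the mirrored orientation. After correction the orient landmark has
out-of-plane coordinate 0 (within 1e-9) and strictly positive in-plane
off-axis coordinate — this one rotation simultaneously removes torsion
and resolves mirroring. It is undefined when the orient landmark lies
on the axis, which raises a degenerate-geometry error naming the
specimen and structure.

**Double-point articulation.** The literature describes two internal
rotations per structure but does not enumerate them; this package fixes
the sequence as (i) hinge-axis alignment, (ii) in-axis torsion removal
via the third role landmark, (iii) placement of structure 2 at θ_T —
the minimal sequence that achieves the standard pose, and identical in
form to the single-point procedure per structure. The fourth role
landmark closes a tetrahedron used for the chirality check.

**Chirality.** There is no absolute handedness reference for an
arbitrary shape, so reflection is defined relationally: within each
structure, the signed volume of the role quadruple must have the same
sign for every specimen. A minority-sign specimen is reported in a
`ReflectionError` rather than silently flipped, because a reflection is
not a rigid motion and "fixing" it would fabricate shape. Single
specimens (and quadruples with near-zero volume) cannot be checked and
pass through.

**Specimen matching.** Datasets are matched by specimen identifier;
the first dataset's order wins (deterministic output order). Specimens
present in only one dataset are dropped with a warning naming them; an
empty intersection is an error.

**Quality screening.** Before rotating, role landmarks are screened
per specimen: an axis pair closer than 1e-6 x centroid size is flagged
coincident; a base/end/orient triple whose angle at the base has sine
below 0.01 is flagged near-collinear (the in-axis correction is then
ill-conditioned). Both thresholds are scale-free; neither blocks
execution — flags surface as warnings. The guidance that the orient
landmark should share a coordinate with the axis end landmark is
recorded as an informational deviation only, since enforcing it would
reject perfectly rotatable real data.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| role indices | landmarks defining axis, orient, chirality | — | 1-based, distinct, per structure |
| `target_angle_deg` (θ_T) | angle between standardized axes | — | 0–360°; the realized inter-axis angle (range 0–180°) equals θ_T for θ_T ≤ 180 and 360 − θ_T above |
| `origin` | translation target point | (0, 0, 0) | any point; coordinates keep input units |
| offset | post-rotation displacement of structure 2 | none | pure displacement; use to separate structures visually |

Angles are degrees throughout the public API; internal mathematics is
in radians.

## Synthetic data generator

`make_articulated_pair` emulates the data situation the method exists
for: one fixed template shape per structure (axis landmarks well
separated, orient landmark off-axis, chirality landmark off-plane),
each specimen observed after an independent uniform random proper
rotation, a translation uniform in (−5, 5) per coordinate, and a joint
angle uniform in a configurable range (default 20–160°, a plausible
joint excursion). Optional isotropic Gaussian noise is applied to
non-role landmarks only, so degeneracy stays controlled. Defaults: 20
specimens, 8 + 10 landmarks, noise 0. Everything is deterministic
under the seed, and the applied transforms are recorded so
pose-invariance and ground-truth recovery are directly checkable.

What the generator does **not** emulate: biological shape variation
between specimens (all specimens share one template), digitization
noise on role landmarks, and landmark-count asymmetries beyond the two
structure sizes. Passing tests therefore demonstrate correctness of the
rigid-motion removal, not robustness of landmark *choice* on noisy real
material — the quality report exists precisely because that choice is
the user's main lever.

## Numerical choices

* arccos arguments clamped to [−1, 1]; parallelism threshold 1e-12 on
  the sine; unit-axis tolerance 1e-9.
* Rotation-matrix invariants (RᵀR = I, det = +1) hold to 1e-9 per
  entry; agreement with an independent quaternion-based oracle to
  1e-9 on random axis/angle/point triples.
* The articulation procedures require the articulation landmark at the
  origin (within 1e-7 x coordinate scale) and raise a guided error
  otherwise; the CLI translates automatically unless `--pre-translated`
  is passed.
* TPS output prints shortest-round-trip float reprs, so
  write-then-read is the exact identity on coordinates and ids, and
  output files are byte-stable.
* TPS reading accepts LF/CRLF, blank lines, case-insensitive keywords,
  `IMAGE=` lines, and a multiplicative `SCALE=`; `SCALE` is never
  written back (rotated coordinates are in final units).

## Problem sizes

The test suite and the acceptance script run on synthetic sets of 1–12
specimens with 8 + 10 landmarks; every quantity measured (realized
inter-structure angle, translation residual, invariance deviations) is
independent of specimen count, which these sizes make easy to see at
machine precision.

## Known limitations

* Exactly two structures per call; chains of more than two articulated
  units are handled by repeated application, not by a dedicated
  n-structure operation.
* θ_T is the user's anatomical judgment; nothing estimates a
  biologically optimal angle, and analyses at more than one angle are
  advisable when the choice is uncertain.
* Reflected input is detected only relationally (needs ≥ 2 specimens
  with valid chirality tetrahedra).
* Only the 3D TPS dialect is supported (no NTS/Morphologika; no 2D
  `LM=` records).
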