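# articulate3d

Standardized rigid rotation of articulated three-dimensional landmark
structures, for geometric morphometrics and any other analysis of 3D
Cartesian coordinate data.

## The problem

Articulated anatomy — a skull and its mandible, a humerus and the
radioulna it meets at the elbow — moves at its joints. When landmarks
are digitized from such structures (e.g. from micro-CT scans), every
specimen carries an arbitrary joint pose on top of its actual shape.
Downstream shape analyses (Procrustes superimposition and everything
after it) cannot distinguish that articulation-induced rotation and
translation from real shape variation, so the pose must be removed
first. `articulate3d` does exactly that: it rigidly translates and
rotates the two structures of each specimen into one standard reference
pose, placed at a user-chosen inter-structure angle θ_T, without ever
altering within-structure shape.

## The method

For a structure with landmarks P = {p₀, …, p_M} (p₀ the articulation
point, p_M the axis end point):

1. **Translate**: T(p̃ᵢ) = p̃ᵢ − p̃₀, so the articulation point sits at
   the origin.
2. **Align**: rotate so the axis p₀→p_M lies along the reference
   direction, using the rotation R(u, v) = R′(N(u, v), ∠(u, v)), where
   N(u, v) = (u × v)/|u × v| is the unit plane normal,
   ∠(u, v) = arccos(u·v / |u||v|), and R′(w, θ) is the Rodrigues
   axis–angle rotation matrix about unit axis w.
3. **Constrain**: spin about the aligned axis by the quadrant-aware
   arctangent of the orient landmark's two off-axis coordinates, so
   that landmark lands in the reference plane with positive off-axis
   coordinate. This removes torsion and fixes the mirroring ambiguity
   of a two-landmark axis.
4. **Place at θ_T**: structure 1's axis goes along (1, 0, 0); structure
   2 is rotated within the XY-plane so its axis points along
   (cos θ_T, sin θ_T, 0) — e.g. (0, 1, 0) for θ_T = 90°.

A **single-point articulation** (shared joint, e.g. elbow) needs three
role landmarks per structure (articulation point, axis end, orient). A
**double-point articulation** (two hinges, e.g. jaw joints) needs four:
the fourth closes a tetrahedron whose signed volume is checked for
handedness consistency across specimens — a reflected specimen raises
an error, because no rigid rotation can undo a reflection.

All transformations are proper rigid motions: pairwise distances and
chirality are preserved to machine precision, only pose changes.

## Worked example

Generate a synthetic articulated pair (known template shape, random
rigid motion per structure per specimen), standardize it at 90°, and
plot one specimen:

```sh
$ articulate3d synth demo --n 3 --seed 4
wrote demo_structure1.tps and demo_structure2.tps (3 specimens, single joint); role landmarks 1,2,3 in both structures

$ articulate3d rotate-simple demo_structure1.tps demo_structure2.tps demo_joined.tps \
      --roles1 1,2,3 --roles2 1,2,3 --angle 90
rotated 3 specimens to 90 deg (single-point articulation); wrote 18 landmarks/specimen to demo_joined.tps

$ articulate3d plot demo_joined.tps --split 8 -o demo.png
wrote demo.png

$ head -4 demo_joined.tps
LM3=18
0.0 0.0 0.0
1.9999999999999996 -3.293962132390388e-16 7.499454306457578e-17
0.5999999999999996 0.9000000000000001 2.3560489300179026e-17
```

Reading the output: the first landmark is the articulation point at the
origin; the second is the axis end on (2, 0, 0) — structure 1's axis is
on the X-axis to ~1e-16; the third is the orient landmark in the
XY-plane at positive y. Structure 2 (landmarks 9–18, drawn in red by
`plot`) has its axis along (0, 1, 0): the two structures meet at
exactly 90°. Role indices are 1-based everywhere, matching
morphometric convention.

The same pipeline is available as a library:

```python
import articulate3d as a3

d1 = a3.read_tps("radioulna.tps")
d2 = a3.read_tps("humerus.tps")
pair = a3.match_datasets(a3.translate(d1, 1), a3.translate(d2, 52))
spec = a3.ArticulationSpec((1, 10, 17), (52, 19, 107), target_angle_deg=90)
joined = a3.simple_rotation(pair, spec)
a3.write_tps(joined, "joined_arm.tps")
```

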