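# Methods

This note documents the geometric models, measurement conventions, default
parameters and numerical choices behind `dentaltrueness`, including the
places where the method leaves genuine design freedom and what was chosen.

## The structurized dental model

Each jaw model is a watertight triangle mesh in mm, occlusal plane parallel
to X–Y and occlusogingival direction along +Z (the printing pose: base on
the build platform). It consists of:

- **14 simulated dental crowns (SDCs)** — right rectangular prisms with a
  vertical axis, one per tooth type and side. Their mesiodistal (MD),
  buccolingual (BL) and crown-height (CH) dimensions are fixed design
  values drawn from population crown measurements; e.g. the maxillary first
  molar is 10 × 11 × 8 mm and the mandibular second molar is 11 × 10 × 12 mm.
  Each SDC contributes six labeled faces (occlusal, buccal, lingual,
  mesial, distal, gingival-contact); the gingival-contact face exists for
  bookkeeping only and is excluded from every metric.
- **A horseshoe-shaped base** (no palatal plate), 5 mm thick, whose upper
  surface `base:upper` is both a registration surface and the
  occlusogingival datum.

The published design gives no arch-layout numbers, so the layout is a
documented default of this package rather than a reconstruction: SDC
centers lie on a parabolic arch centerline `y = -c·x²` (c = 0.018 mm⁻¹,
apex curvature radius ≈ 28 mm), placed by arc length with a 2 mm gap
between neighbours and across the midline, mesiodistal axis along the arch
tangent and buccolingual axis along the outward normal; the base band
extends 8.5 mm to each side of the centerline with semicircular end caps.
Trueness metrics compare measured against *designed* values, so they are
insensitive to the specific layout as long as the schema is derived from
the same layout that generated the mesh — which it is, by construction.
The 12 arch dimensions (L1–L12) are therefore recorded in the schema with
designed values derived deterministically from the layout.

Meshes are built as lattices with a configurable facet size (`patch_mm`,
default 2 mm) so that deformations can bend surfaces smoothly; every
reference metric is exact at any resolution. The model is a disjoint union
of closed solids (base + 14 crowns) rather than a boolean union: each
component is watertight with outward orientation, which is equivalent for
every metric defined here and keeps construction exact. Binary or ASCII
STL export is paired with a JSON sidecar mapping region names to face
indices (STL preserves face order, making the sidecar stable across round
trips).

## Measurement schema: 96 feature sizes

Per jaw: 14 MD + 14 BL + 14 CH + 6 arch dimensions = 48; 96 over both
jaws. MD/BL and the arch dimensions are *occlusal-plane* (in-plane)
quantities (34 per jaw); CH is *occlusogingival* (14 per jaw). Every
occlusal-plane measurement direction lies strictly in the design X–Y plane
(face centers of an arch pair differ in height, so the raw center-to-center
direction would mix axes and break the clean separation of X–Y and Z
printing errors). The arch dimensions are all outer spans (e.g. L1 spans
the first and second molars from mesial-FM to distal-SM; L3 spans the four
incisors distal-to-distal; L11/L12 are the cross-arch widths between
second-molar buccal faces).

## Virtual caliper

Physical protocol context: linear dimensions are taken directly on the
printed model with a hand caliper — no scan, no registration. The virtual
caliper is therefore *intrinsic* to the test mesh:

- the occlusogingival datum is the unit normal **n** of the orthogonal
  least-squares plane of the test mesh's own `base:upper` region, oriented
  toward the crowns;
- each defining surface is contacted at its area-weighted mean point
  (equivalently: its best-fit plane evaluated at its centroid);
- CH = n · (c_occlusal − c_base); MD/BL = the in-plane component of
  (c_b − c_a) projected on the in-plane direction of the two opposing
  faces' mean outward normals; arch dimensions = the in-plane norm of
  (c_b − c_a). A negative raw span (surfaces inverted along the axis) is
  flagged as a measurement failure.

These conventions were chosen over an extreme-point ("rigid jaw") contact
deliberately. Mean-point contact is (i) exact on the designed geometry to
1e-9 mm, (ii) exactly invariant under rigid motion of the model, (iii)
exactly equivariant under in-plane/axial scaling — an xy scale of s makes
*every* occlusal-plane relative error (s−1)·100% identically — and (iv)
unbiased under zero-mean surface/scan noise. An extreme-point contact
inherits an extreme-value bias of roughly σ·√(2 ln N) per jaw face from
noise with standard deviation σ over N surface points (≈ +50 μm per face at
σ = 20 μm), which would systematically corrupt recovered scale errors; on
smooth deformations both conventions agree. The trade-off: localized
outlier bumps a physical caliper would catch are averaged away — they show
up in the deviation map and flatness instead.

Relative error is (x₂ − x₁)/x₁ × 100% (positive = enlargement). Jaw-level
aggregation: mean ± sample SD (n−1) of the 34 occlusal-plane and of the 14
occlusogingival relative errors. ICC uses the two-way random-effects,
absolute-agreement, single-measures estimator, computed from the standard
ANOVA mean squares; the same estimator serves intra- and inter-examiner
matrices.

## Registration and 3D deviation

Best-fit registration is point-to-plane ICP of area-weighted surface
samples of the test mesh against the reference surface, restricted to the
base upper surface and each crown's occlusal, buccal and lingual faces
(mesial/distal faces are excluded: interproximal gaps scan poorly, and the
published protocol excludes them for that reason). The pose is seeded by a
principal-axes pre-alignment whose axis signs are disambiguated by the
third central moments of the vertex distribution (anterior-posterior and
base-crown asymmetry); degenerate inertia falls back to the identity with
a warning. Correspondences are rejected when the source and target normals
disagree (dot ≤ 0.5) or the distance is a gross outlier (> max(5·median,
0.5 mm)) — necessary when the test mesh carries no labels and its base
bottom/walls would otherwise latch onto the restricted reference surface.
Convergence: change in RMS residual < 1e-7 mm, cap 200 iterations;
non-convergence is flagged on the result and exits non-zero in the CLI.
Scale is never solved for — a rigid fit must not absorb the shrinkage the
method measures; a uniformly scaled model therefore leaves a visible
residual.

Signed deviations are sampled on the test regions (default 25 points/mm²,
a ~0.2 mm grid commensurate with a 20 μm scanner), measured to the nearest
point of the reference regions, signed by the reference outward normal
(positive = material excess/expansion). RMS follows the standard formula;
the **overall value** is the arithmetic mean of the two jaw RMS values
(this convention reproduces published aggregate examples, e.g. jaw values
of 47 and 43 μm giving 45). Closest-point queries use a centroid k-d tree
with an exact fallback radius, so distances are exact at every resolution
(`rtree`-backed proximity structures are not required).

The 21-segment color map places the closed nominal band [−0.05, +0.05] mm
in the middle bin and splits each side into 10 equal-width bins out to the
±0.50 mm critical value, clamping beyond; bin assignment is monotone in the
deviation. Colors run blue (contraction) through green/yellow to red
(expansion).

## Form errors

Planes are orthogonal least-squares fits (smallest right singular vector of
the centered points); degenerate (collinear) inputs are rejected. Flatness
is x₊ + x₋ over the region's sampled points — the best-fit-plane form
deviation, *not* the ISO minimum-zone envelope. Per jaw: 42 flatness values
(occlusal + buccal + lingual × 14 crowns), with horizontal (14) and
vertical (28) means also reported; parallelism = acute angle
arccos|n₁·n₂| between each occlusal plane and the base plane (14 values);
perpendicularity = |angle − 90°| for each buccal/lingual plane (28 values).
Both angle metrics derive from the same acute-angle definition. Summaries
are mean ± sample SD.

Surface sampling consumes randomness face by face with stochastic rounding
of each face's expected count (area × density), which makes a rigidly moved
mesh yield exactly the rigidly moved samples — flatness and angles are then
rigid-invariant to machine precision, and sampling is deterministic given a
seed.

## Synthetic deformations

`apply_deformation` composes, in a fixed documented order: anisotropic
scale about the vertex centroid (xy_scale on X–Y, z_scale on Z) → basal
warp z += k·r² about the centroid axis → Gaussian noise along the deformed
surface's vertex normals → a small rigid jitter (rotation angle in degrees
and translation components drawn with SD `rigid_jitter`). Labels ride
along unchanged. The default fixture grid covers pure in-plane shrinkage
(0.99), pure axial shrinkage (0.995), pure warp (5e-5 mm⁻¹ ≈ tens of μm of
basal bowing over the horseshoe), the combination, and the combination
with 20 μm noise plus jitter — magnitudes of the order reported for
desktop photopolymer printers (tens of μm form error, up to ~1% linear
error). What this emulates — and what it does not: global scale errors,
symmetric basal bowing and scanner-like surface noise are represented;
layer-wise staircase artifacts, local cure-depth variation, support marks
and anisotropic in-plane distortion are not. Passing closed-loop tests
therefore demonstrates that the *evaluation chain* is unbiased and exact
under these deformation modes, not that any physical printer behaves this
way.

## Numerical and degenerate-input conventions

- All geometry in float64 mm; designed-vs-measured agreement on references
  is asserted at 1e-9 mm.
- STL vertices are deduplicated within 1e-6 mm on read; malformed binary
  STL reports the failing byte offset.
- Label transfer assigns each test face the region of the nearest
  orientation-compatible reference face (orientation penalty
  cutoff·(1 − n·n'), cutoff 0.5 mm); coincident-surface ties (crown bottoms
  on the base top) break toward the nearest face centroid, making transfer
  of a mesh onto itself the identity. Faces beyond the cutoff stay
  unassigned.
- Empty meshes, empty region selections, zero sampling densities,
  incomplete feature sets and incomplete ICC matrices raise errors naming
  the offending object; they are never silently skipped.
- Report JSON stores full-precision values plus a display block rounded to
  the conventional precisions (integer μm; 3 decimals for mm and degrees;
  2 decimals for percent). No timestamps: identical inputs, config and
  seed give byte-identical reports.

## Problem sizes used in tests and the acceptance script

Reference meshes at the default 2 mm facet size have ≈ 7 500–8 000 faces
per jaw; registration uses 3 000 samples (1 500 in the fast test
configuration), deviation/form sampling 2–8 points/mm² in tests against a
default of 25. The closed-loop statistical check runs 20 noisy fixtures of
the maxillary jaw at 20 μm noise. These sizes were chosen because every
exactness property is resolution-independent (asserted at machine
precision), so finer meshes only add cost, not information.

## Known limitations

- Cuboid crowns and a flat base probe printer trueness on planar,
  axis-aligned geometry only; anatomic morphology, undercuts and thin
  features are outside the model (as in the underlying method).
- The mean-point caliper does not feel localized peaks (see above).
- Best-fit registration of a *deformed* model is itself part of the
  measurand: for non-rigid deformations the registered pose — hence the
  deviation RMS — depends on the selected regions, exactly as with
  commercial best-fit software; linear and form metrics are deliberately
  registration-free.
- The ICC is implemented for complete matrices only.
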