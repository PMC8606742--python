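# Methods

## Kinematic model

Bones are rigid bodies tracked by ≥3 non-collinear markers each; their
per-frame transforms are recovered by orthogonal Procrustes (Kabsch) fits
with det +1 enforced, so a reflection can never be returned. Collinear
marker sets are rejected outright: rotation about the marker line is
unobservable, the failure mode that in practice forces a poorly markered
bone to be animated with its neighbour's transforms.

Joint pose is the distal anatomical frame expressed in the proximal one.
Rotations are decomposed as **intrinsic Euler angles applied X then Y
then Z** (abduction-adduction, long-axis rotation, flexion-extension).
The source tooling's rotate order is not documented anywhere authoritative,
so the order is an explicit, configurable assumption recorded in every
`JointPose`; silently mixing orders is the classic way such comparisons go
wrong. Translations are the distal origin in proximal coordinates (mm),
matching the cranial/caudal (X±) sign semantics of the excursion table.
Angles live in (−180°, 180°]. Gimbal lock (middle angle within 1e-6° of
±90°) is flagged and broken deterministically: the third applied angle is
set to zero and the first is solved exactly from the residual rotation, so
recomposition still reproduces the matrix.

Kinematic series are filtered with a 4th-order Butterworth low-pass applied
forward and backward (zero phase, reflective padding, unit DC gain). The
study protocol this emulates used trial-dependent cutoffs of 3–8 Hz at
60 frames/s; the cutoff is a required argument, not a default.

## Geometric moment arms

For each joint axis the vector moment arm is the common perpendicular
between the axis line and the straight muscle line; the scalar moment arm
scales its length by the in-plane fraction of the muscle direction and
signs it by the right-hand rule:

    r_θ = sign((r × F̂)·â) · ‖r‖ · ‖F̂ − (F̂·â)â‖

This equals the triple product ((p − a) × F̂)·â algebraically, so it is
independent of marker spacing and of which point of the line is marked;
both facts are asserted as properties. Parallel axis/muscle pairs are
flagged degenerate and return exactly 0 (the in-plane fraction vanishes).

**Sign contract.** `scalar_moment_arm` reports torque per unit force
directed from `p_prox` to `p_dist`; swapping the markers negates every
value. The leverage of the muscle's pull on the bone carrying `p_dist` is
the moment arm of the reversed line (`MuscleLine.flipped()`), and it is in
that orientation that the geometric method coincides with tendon travel.
The orientation is kept explicit rather than baked in because both
conventions are used in practice and a hidden flip is harder to audit than
a documented one.

Joint axes are evaluated on the proximal bone's animated frame by default
(`axes_from="proximal"`), since anatomical axes are fixed on bones; the
distal frame is available as a configuration for sensitivity checks.

## Tendon-travel cross-estimator

The independent estimator is tendon travel, r_θ = −dL/dθ, computed by
central differences with h = 0.01° by default. No numerical scheme is
prescribed by the biomechanics literature for this; the O(h²) truncation
error at this step size is ~1e-6 mm for desk-scale rigs, three orders below
the 0.1 mm reporting precision of moment-arm tables, and the minimum
accepted step (1e-6°) guards against float cancellation. Agreement of the
two estimators across randomised single-DOF rigs is the package's core
validation property.

## ROM summaries and envelopes

Per-specimen excursions pool by taking the minimum of minima and maximum of
maxima per DOF; the "total possible" range is their spread, invariant to
record order and duplication. Translation DOFs additionally report the mean
of per-specimen totals.

Pose clouds (rx, ry, rz in degrees) may be cosine-corrected before hulling:
the corrected coordinate is multiplied by the cosine of a modulating
coordinate, de-distorting Euler-space distances. Defaults correct the axis
of greatest variation (X) by the long-axis rotation (Y); published
descriptions name only the corrected axis, so the modulating axis is an
explicit parameter. Double correction is rejected via a flag on the cloud.

Envelopes are Delaunay alpha shapes: tetrahedralise, retain tetrahedra by
the alpha criterion, sum their volumes (cubic degrees), extract boundary
facets as faces used by exactly one retained tetrahedron. Two alpha
dialects exist in the wild; the default retains tetrahedra with
**circumradius ≤ alpha** (threshold 20 commensurate with degree-scaled
axes), the reciprocal dialect (≤ 1/alpha) is available, and the dialect
used is recorded in the envelope and its JSON export. Volume is
non-decreasing in alpha and bounded by the convex hull volume, both
asserted as properties. The envelope is computed on the three rotational
coordinates only; translations are summarised separately. Single-axis model
ROM limits are compared against an envelope by bisection along each axis
ray from the reference pose; for a non-convex envelope this reports the
first boundary crossing, which is the conservative choice.

## Torque layer

Maximal isometric force is PCSA × 0.3 N/mm² (standard vertebrate specific
tension). Torque about a DOF is

    τ_θ = r_θ · F_max · [a · fl_act(ℓ̃) + fl_pass(ℓ̃)] · cos(pennation)

with activation a ∈ [0, 1] and ℓ̃ the fibre length normalised to optimal,
obtained under a rigid-tendon assumption: (musculotendon length − tendon
slack length)/cos(pennation)/ℓ_opt — the simplest defensible model when no
tendon compliance data exist. The musculotendon curves are generalised,
not species-specific: Gaussian active force-length (peak 1 at ℓ̃ = 1,
width 0.45 normalised lengths), exponential passive curve engaging above
ℓ̃ = 1 and reaching 1 at ℓ̃ = 1.7, linear-region tendon (3.3% strain at
F_max), and a Hill force-velocity curve that is stored but unused — the
analysis is purely isometric. Any curve can be replaced by a tabulated
interpolant. Multi-head muscles are averaged within their head group before
summation so muscles modelled as several lines of action are not
over-counted; peak rank orders break ties alphabetically.

## Synthetic rigs

The simulator emulates the cadaver-trial data the pipeline consumes: a
static proximal bone, a distal bone articulated by a revolute, ball, or
6-DOF joint, straight point-to-point muscles, three non-collinear markers
per bone plus proximal/distal muscle-belly markers, 60 frames/s, and iid
isotropic Gaussian marker noise. The default noise scale in examples is
0.1 mm — below the 0.8–1 mm marker diameters that bound plausible tracking
error — and every trial records its seed. What the simulator does *not*
emulate: marker migration within soft tissue, skin/ligament constraint,
curved muscle paths around bone (the geometric method itself assumes a
straight line of action), or fluoroscope-specific tracking error structure.
Passing recovery tests therefore demonstrates correctness of the
computational chain, not robustness to those biological error sources.

## Problem sizes and numerical choices

Validation runs use desk-scale problems chosen to make the mathematical
properties sharp: 1000 random poses for Euler round-trips (error < 1e-9),
200 random skew pairs against a refined 2000×2000 grid search (1e-3 mm),
500 random configurations against the lever oracle (1e-9 mm), 100 random
single-DOF rigs × 36 poses for method equivalence (1e-4 mm at h = 0.01°),
600-frame hinge trials for parameter recovery (exact to 1e-6 mm noise-free;
mean error within 3 standard errors at σ = 0.1 mm), and hull fixtures of
~1000 (cube) and ~5000 (L-prism) points, where the alpha hull lands within
5% and 10% of the analytic/voxel-oracle volumes respectively. The published
envelope volumes for real shoulder and elbow trials cannot be reproduced
here because the underlying trial point clouds were never deposited; the
packaged reference data are the per-specimen excursion table only.

One discrepancy in that table is preserved rather than patched: the
glenohumeral abduction-adduction row pools to −57…44°, a 101° spread (the
value the source text also states), while the table's printed total for
that single row is 100° — a rounding artefact of pooling unrounded data.
All other pooled totals and both translation means reproduce the printed
values exactly.

## Known limitations

Straight-line muscles only (no via points or wrap surfaces); isometric
torque only (no activation or contraction dynamics); envelope overlay
assumes the reference pose lies inside the envelope; `.mot` export targets
the minimal common header dialect (name/datacolumns/datarows/range) rather
than every SIMM version's variant.
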