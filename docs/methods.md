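# Methods

## The volume model

An acquisition produces M same-sized RGB images, one per milling pass.
`RasterVolume` treats them as a node-centered anisotropic grid: pixel
(i, j) of layer k (1-based) sits at world coordinates
(x, y, z) = (j·pitch, i·pitch, (k−1)·Δz) in μm, so each layer image lies
exactly on its plane z = Z_k.  The node-centered convention was chosen over
cell-centered so that layer-plane sections can be bit-exact reproductions
of the source images (see *Reslicing*).  The volume box is
[0, (W−1)·pitch] × [0, (H−1)·pitch] × [0, (M−1)·Δz]; points outside it
sample a configurable `fill_color` (default black), so sections extending
past the box render deterministically.

Two sampling modes are provided.  `nearest` rounds fractional grid indices
half-up and returns the stored voxel color; `trilinear` interpolates
bilinearly in-plane and linearly between the two bracketing layers, in
floating point, quantizing half-up to 8 bits on output.  The acquisition
chain never specifies an interpolant between milled surfaces; trilinear is
the simplest scheme consistent with interpolating "between each adjoining
pair of images", and it reproduces any color field that is affine in
(x, y, z) to within the half-level quantization bound.  At grid nodes the
two modes agree exactly.

Layers are accessed through a loader interface — fully in memory
(`ArrayLayerLoader`) or decoded per layer on demand (`FileLayerLoader`) —
with identical sampling semantics, because real stacks (thousands of
multi-megapixel layers) do not fit in RAM while test stacks do.  Sampling
batches voxel lookups by layer index so a lazy loader touches each file
once per query.

## Section frames

A section plane Ax + By + Cz + D = 0 (μm) carries two orthonormal in-plane
frames, each fixed by one linear constraint plus unit length:

* (ξ, η), with ξ_y = 0:  ξ = {C, 0, −A}/√(A²+C²),  η = (ξ×n)/|ξ×n|;
* (p, q), with p_z = 0:  p = {−B, A, 0}/√(A²+B²),
  q = {−AC, −BC, A²+B²}/M_q,  M_q = √(A²C² + B²C² + (A²+B²)²),
  equivalently q = (n×p)/|n×p|.

(p, q, n̂) is right-handed (p × q = n̂).  The (p, q) frame is the rendering
frame: its scanlines keep consecutive section pixels on nearby stack layers,
which is the disk-access-friendly "natural pixel bypass" order for stacks
stored one file per layer.  Both frames are invariant under positive
rescaling of (A, B, C, D).

Degenerate orientations use fixed fallbacks, triggered when √(A²+C²) or
√(A²+B²) < 1e-12·‖(A,B,C)‖: planes with normal along y take ξ = e_x;
horizontal planes (normal along z — the most common slicing request) take
p = e_x and q = n̂ × p, which for C > 0 gives (p, q) = (e_x, e_y), i.e. the
image axes of the source layers.

The plane–volume intersection polygon (3–6 vertices for a proper cut) is
computed by clipping the 12 box edges against the plane, de-duplicating,
and ordering vertices counter-clockwise about +n̂.  Grazing contacts
(corner or edge only) are reported as empty.

## Reslicing

`render_section` lays the section image out in (p, q): pixel (r, c) has its
center at (u, v) = ((c+0.5)·pitch, (r+0.5)·pitch) from the section origin,
which is anchored at the minimum corner of the (u, v) bounding rectangle of
the intersection polygon so all section coordinates are non-negative; v
grows downward in the saved image.  Default section pitch equals the volume
pitch — no resolution is invented beyond the data.  Pixels outside the
polygon or box render `fill_color`; the mask distinguishes them.  A plane
that misses the volume produces an empty image and a warning rather than an
error, because plane sweeps legitimately leave the box.

Half-pixel centering and node-centered storage are incompatible with exact
layer reproduction, so sections that coincide with a source layer plane
(axis-aligned, |z − Z_k| < 1e-9, positive C, pitch equal to the volume
pitch) snap sampling to the source grid nodes and return the stored layer
bit-exactly.  This exactness fast path never affects oblique planes.

## Medium removal and alignment

The embedding medium appears as a near-uniform background.  Its color is
estimated as the per-channel median over the four 8×8 corner patches of all
layers — robust to a specimen touching some corners and to sensor noise.
A pixel is specimen iff its Euclidean RGB distance to the medium color
strictly exceeds a threshold (default 30 of 255, configurable); per-layer
cleanup can remove small components or keep only the largest.  Medium
removal replaces out-of-mask pixels, by default with the medium reference
color itself so that re-masking the cleaned volume is idempotent.

Camera jitter between passes is modeled as pure 2D integer translation —
the camera is fixed outside the chamber, so rotation and scale are
excluded.  `estimate_shift` exhaustively maximizes normalized
cross-correlation over a shift window (ties break toward the smallest
displacement; optional parabolic sub-pixel refinement), and `align_stack`
chains each layer to its already-aligned predecessor, matching the
incremental acquisition.  The search window extends 4 px beyond the
configured clamp so over-limit shifts are detected, clamped and warned
about rather than silently capped.  Correlation-based translation stands in
for the unspecified "outline matching" step; deformable or contour-based
registration is out of scope.

## Morphometrics

**Radial thickness.**  Sample points are spread uniformly by arc length
along the outer boundary; at each, both normal directions are probed and
the nearer positive intersection with the inner boundary is recorded, so
the measure does not depend on contour orientation.  Rays that miss are
excluded and counted.  Tangents are estimated by a central secant over ±3
mean segment lengths of arc, which suppresses the staircase jitter of
pixel-traced contours while leaving dense analytic polylines untouched.
The summary is median [Q1, Q3]; mean ± SD is carried alongside.

**Surface factor.**  Walking from the first vertex, consecutive reference
points are placed where the straight-line (chord) distance from the
previous reference first reaches the spacing (default 100 μm; chord
spacing, not arc, matching "points at a distance of … from each other").
Each factor is arc length / chord length between the pair; arc ≥ chord
guarantees factor ≥ 1, and straight borders score exactly 1.  Per-segment
values are retained; the arithmetic mean is the default aggregate.

**Boundaries** are sub-pixel marching-squares contours (level 0.5) of the
binary mask, zero-padded so regions touching the frame close properly.
Marching squares on unsmoothed binary data overestimates a curved
boundary's length by a few percent (≈6% for a 40 px-radius disc) — a known
staircase bias that inflates raster-measured surface factors by the same
order; analytic-polyline measurements are unaffected.

**Optical density** is I = 0.299R + 0.587G + 0.114B of the region's mean
channel values — the luminance proxy used for extracellular-matrix density
in stain-free reconstructions.

**Mann–Whitney U** uses midranks (ties supported); U is min(U_a, U_b).
For combined n ≤ 16 the two-sided p is exact: the fraction of all
C(n, n_a) labelings whose U_a deviates from n_a·n_b/2 at least as much as
observed (equals the doubled-tail convention when tie-free; remains
well-defined with ties).  Above that, a normal approximation with tie and
continuity correction is used.  The switch point balances exactness against
the C(16, 8) = 12,870 enumerations it costs; the procedure is seedless and
deterministic.

## Phantoms

Phantoms emulate the capture chain — scene, then camera motion, then sensor
noise.  A layer is the analytic cross-section of a solid at z = (k−1)·Δz,
rasterized with a center-in-shape rule (no partial coverage, so pixel
counts are exactly predictable; anti-aliasing is deliberately absent),
composited in integer arithmetic on the medium color, shifted by logged
integer jitter (layer 1 pinned at zero, vacated pixels filled with medium),
and finally corrupted by clipped additive Gaussian noise.  All randomness
comes from one seeded NumPy PCG64 generator with a fixed draw order
(texture, jitter, per-layer noise), so identical spec + seed give
bit-identical stacks.

Defaults mirror the real rig scaled to test size: Δz = 10 μm, pixel pitch
8 μm, 256×256 canvas, medium (200, 200, 210), specimen (150, 80, 60).  The
cartilage plate defaults to 232 μm thickness — the headline cartilage
value — with an optional sinusoidal outer border whose analytic surface
factor is available by quadrature (`sinusoid_surface_factor`,
scipy quadrature + root solving, independent of the polyline measurement).
An optional smooth "texture" field (bilinear upsampling of a coarse seeded
grid, shared by all layers like a real extruded scene) gives registration
something to lock onto; scale-2 px texture makes the correlation peak sharp
enough for exact integer recovery under σ = 5 noise.

Sphere and shell interiors are closed (boundary pixels are specimen), so a
radius-R ball spans exactly 2R/Δz + 1 non-empty layers when R is a multiple
of Δz.  The slab thickness interval is half-open ([y_out, y_out + t)),
which centers the traced boundary pair on the true faces and removes the
one-pixel bias a closed interval would add to measured thickness.

What the phantoms do **not** emulate: real tissue texture and color
heterogeneity, milling grooves, ice-crystal artifacts, lighting drift, or
partial-volume blur at specimen edges.  Passing tests therefore demonstrate
the correctness of the geometry, sampling, registration and measurement
code under the stated capture model — not segmentation robustness on
difficult real-world boundaries, which the acquisition literature itself
flags as imperfect.

## Problem sizes and numerical choices

Test and acceptance workloads are scaled to run in seconds: phantom
canvases of 48–256 px, 2–35 layers, 32³ random volumes for oracle
comparisons, 10,000 random planes for frame invariants, 20 phantom seeds
for jitter recovery, and all sample-size pairs with n_a + n_b ≤ 10 for the
exact-test enumeration.  Frame orthonormality holds at 1e-9 (observed
≈ 4e-16); plane/box vertices satisfy the plane equation to 1e-6 relative;
quantization is round-half-up throughout; degeneracy detection uses a
1e-12 relative threshold.  Thickness is recovered within one pixel pitch,
sphere section radii within one pitch (observed ≈ 0.13 px), and the
layer-identity, renderer-oracle, jitter and determinism checks are exact.

## Known limitations

* Only the axis-aligned volume box is cut; arbitrary polyhedral (wireframe)
  models and curved cut surfaces are not supported.
* Registration is integer/sub-pixel translation only.
* Raster-traced boundaries carry the marching-squares staircase bias noted
  above; surface factors measured on 8 μm-pitch masks are upper bounds.
* The exact Mann–Whitney p enumerates C(n, n_a) labelings and is capped at
  combined n = 16 by design.
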