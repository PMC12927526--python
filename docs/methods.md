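# Methods

This note documents the models, conventions and numerical choices behind
`mitometrics`, and what the synthetic phantoms do and do not establish about
real volume-EM data.

## Conventions

All volumes are carried as `(z, y, x)`-ordered integer (labels) or float32
(images) grids with physical voxel spacing in nanometres. NIfTI's natural
`(x, y, z)` axis order is transposed on read and restored on write, so all
morphology and evaluation code sees one convention. Instance labels are
non-negative integers with 0 as background; on disk they are uint16
(`.nii.gz`), and writing a volume with a label above 65535 is an error that
directs the user to reindex first. Spacing is metadata: it travels through
every operation and drives resampling, but the morphological indices are
computed in voxel units (see below).

## Difficulty indices

Both indices use a cubic structuring element of integer radius $r$ (default
1, i.e. a 3×3×3 box — the full 26-neighborhood). Dilation is the set of
voxels within Chebyshev distance $\le r$ of the mask, clipped at the volume
bounds. Erosion keeps voxels whose full box neighborhood lies inside the
mask, treating outside-volume as background, so voxels on the volume border
always erode; this choice is stated explicitly because it changes EFI for
instances that touch the border, and no border exclusion is applied —
border-touching instances are scored like any other.

**DCI** (Dilation Collision Index): the number of *distinct* other instance
labels intersected by the dilated mask. Each neighbor counts once however
large the contact area. DCI is non-decreasing in the radius, and at radius 1
it is symmetric for mutually 26-adjacent instances.

**EFI** (Erosion Fragility Index): `max(0, components(eroded mask) - 1)`
with 26-connectivity components (configurable; chosen to match the full-box
structuring element). The `max(0, ·)` clamp handles instances that erode to
the empty set — a one-voxel-thick sheet or filament vanishes entirely, and a
vanished object creates no fragments, so it scores 0 rather than −1.

**Anisotropy.** The 3×3×3 element is defined in voxel units even for
anisotropic (e.g. 8×8×30 nm) data: one voxel of boundary uncertainty is one
voxel regardless of its physical size, which matches how segmentation
models make boundary errors on the native grid. An anisotropy-aware
footprint (per-axis radius scaled by the spacing ratio) is exposed on
`StructuringElement` for exploration but is off by default.

**Implementation.** Each instance is processed inside its bounding box
padded by the radius. This is exact, not approximate: a radius-$r$ dilation
cannot reach farther than $r$ voxels beyond the box, and erosion only
shrinks; equality with whole-volume computation is tested against
coordinate-set oracles on random volumes.

## Two-tier evaluation

**Semantic accuracy** binarizes both volumes (any positive label →
foreground) and reports `TP/(TP+FP+FN)` over voxels — Jaccard of the
foreground sets.

**Instance accuracy** builds the dense ground-truth × prediction IoU matrix
in one sparse pass over foreground voxels, solves the optimal one-to-one
assignment with the Hungarian algorithm on cost $-\mathrm{IoU}$ over the
full rectangular matrix, and *then* discards assigned pairs with IoU < τ.
The assign-then-threshold order matters: it is possible for the
maximum-total-IoU assignment to contain a sub-threshold pair whose
alternative would have passed, and the tests pin this order against a
factorial-enumeration oracle. Sub-threshold entries are not pre-masked by
default; a `premask=True` flag zeroes them before solving for comparison
with tools that do. The threshold is inclusive: IoU = τ counts as matched.
Id lists are sorted ascending before solving so solver tie-breaking is
reproducible; TP/FP/FN counts are identical across equal-cost optima when
IoU values at the threshold are distinct.

**Degenerate inputs** are resolved explicitly rather than left as 0/0: both
sides empty → accuracy 1.0 (nothing to find, nothing found); instances on
exactly one side → 0.0.

**Size stratification** uses voxel-count bins with default edges
(500, 5 000, 50 000) — the lowest edge matching the annotation minimum, the
others decade-spaced. Matched pairs and unmatched ground truth are binned by
the ground-truth instance's size (ground truth defines the reference
population); unmatched predictions by their own size, since they have no
ground-truth counterpart.

When several test volumes are scored, TP/FP/FN should be pooled before the
ratio rather than averaging per-volume accuracies; the per-instance match
table export makes either aggregation possible downstream.

## Standardization

- **Reindexing** assigns consecutive ids 1..N by first voxel occurrence in
  (z, y, x) lexicographic scan order — deterministic across runs and
  platforms — and returns the old→new map.
- **Minimum-volume filtering** removes instances below 500 voxels by
  default, inclusively: an instance of exactly 500 voxels survives. The
  filter is idempotent, and the log records the resolution (spacing) at
  which it ran, since a voxel-count threshold means different physical
  volumes at different spacings.
- **Image resampling** uses linear interpolation; when downsampling, a
  Gaussian anti-aliasing prefilter with sigma proportional to the per-axis
  downsampling factor is applied (the conventional choice where the
  prefilter is otherwise unspecified). Output extent per axis is
  `round(extent × spacing_in / spacing_out)`. Anisotropic volumes are left
  at native spacing unless a target is requested.
- **Label resampling** is nearest-neighbor, which can never invent a label
  value; a majority-vote mode over source blocks is available for integer
  downsampling factors (ties go to the smallest label via the mode's
  deterministic ordering).
- **Topology check**: per-instance 26-connected component counts; ids with
  more than one component are flagged as annotation-consistency violations.

## Synthetic phantoms

The generator rasterizes analytic primitives — Euclidean balls, capsule
tubes, dumbbells (two cubes joined by a square-section neck), and Y-shaped
capsule unions — by inequality evaluation on the voxel grid, avoiding mesh
voxelization ambiguity. Placement is rejection sampling with a minimum
Chebyshev gap constraint (gap 0 allows abutting, never overlap); infeasible
packings raise an error reporting the achieved count. Two constructions have
difficulty values known by design: face-abutting cube pairs give every
member DCI ≥ 1 at radius 1, and neck-radius-1 dumbbells with cube sides ≥ 5
give EFI ≥ 1. All randomness flows from a single seeded NumPy generator;
identical (spec, seed) reproduce bit-identical volumes, and fixture
`dataset.json` files embed the generating spec and seed.

Degraded predictions are produced by events drawn per instance — drop,
axial-median split, pairwise merge (relabeling), boundary erosion/dilation
noise, plus spurious background blobs — under a deliberate non-interaction
discipline: each ground-truth instance participates in at most one event,
boundary dilations only claim voxels that are background in both volumes,
and injected blobs keep a one-voxel gap from everything. Under that
discipline the IoU matrix is block-diagonal over events, the global optimal
assignment decomposes, and the event log predicts the exact instance-level
TP/FP/FN of a subsequent evaluation from recorded voxel counts alone (e.g. a
split's fragments partition the original, so fragment IoUs are
`size/orig_size`). The tests and the acceptance script verify this equality
exactly over seeded ensembles.

**What the phantoms do not show.** Intensity channels are a smoothed label
indicator plus Gaussian noise — sufficient for I/O, layout and checksum
testing, with no EM texture, membrane ambiguity, or staining variation.
Phantom shapes are idealized convex-ish primitives; real mitochondria have
fenestrations, nanotunnels and contact-site geometry the primitives only
caricature. Passing the phantom suite therefore certifies the *metrics and
plumbing* (exactness of morphology, matching, bookkeeping, formats), not
segmentation performance on real tissue.

## Problem sizes and numerics

Oracle-equivalence checks run on 100 random volumes of 16³ voxels with up to
10 instances (the brute-force coordinate-set oracles are O(voxels × 27) in
Python, which bounds the practical volume size) and 500 random IoU tables up
to 6×6 (factorial enumeration). Perturbation-recovery ensembles use 50
phantoms of 48³ with 6 instances. IoU comparisons in tests use exact integer
voxel arithmetic wherever possible; assignment totals are compared at 1e-9.
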