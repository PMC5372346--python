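# Methods

## Problem and model

The tracer converts a 3D grayscale stack (8-bit intensities, voxel grid)
into a rooted SWC morphology. Its underlying model of a neuron image is a
density one: neurite segments are regions of high intensity and high voxel
density, so the modes of the foreground voxel distribution lie along the
skeleton, and the spatial arrangement of foreground between two skeleton
nodes carries the shape information needed to decide whether they belong
to the same segment. The pipeline estimates modes by mean shift, prunes
redundant nodes, and connects the survivors with a minimum spanning tree
whose edge weights are *pathway lengths* — the accumulated length of a
sphere walk through foreground — rather than Euclidean distances. A failed
walk is interpreted as a gap and weighted by a large penalty, so the tree
prefers routes through solid signal.

## Coordinate and data conventions

Coordinates are 0-based voxel indices in an `(x, y, z)` frame, `x` fastest
within a slice, `z` the slice index; TIFF pages are `(z, y, x)` and
transposed on read. No physical voxel size is applied; all lengths are in
voxels. Comparisons with SWC files from other tools may need an axis flip
or unit scaling; the package never guesses one. 16-bit input is min-max
rescaled to [0, 255] so the default intensity threshold keeps its meaning.
SWC radii are at least 1.0 — a foreground node is never smaller than one
voxel.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| intensity threshold | 30 | intensity | bright/dark split |
| ratio threshold | 0.3 | — | max dark/bright over 26 neighbors |
| mean-shift sphere radius | 5 | voxels | local-mean support |
| mean-shift max iterations | 100 | — | endless-loop guard |
| kernel scale C | 1.0 | — | Gaussian exponent scaling |
| convergence tolerance | 0.5 | voxels | "cannot shift one step" |
| cover threshold | 3 | voxels | pruning clearance `D − (r₁+r₂)` |
| walk sphere radius | 2 | voxels | pathway step support |
| quadrants | 4 | — | forward-hemisphere split |
| gap penalty M | 100 | — | failed-walk weight multiplier (must be > 10) |
| pair cutoff | 40 | voxels | skip walks for distant pairs |
| min spur length | 5 | voxels | post-hoc spur trimming |
| metric resample step | 1.0 | voxels | density-independent scoring |
| visible threshold | 2.0 | voxels | "noticeably different" distance |

The cover threshold reflects the rule of thumb that detail below ~3 voxels
is not visually distinguishable; C is exposed because no reference value
exists for it.

## Numerical and algorithmic choices

**Binarization.** The dark/bright ratio is oriented as dark/bright and
compared with ≤, so voxels mostly surrounded by dark neighbors (isolated
noise) are rejected — the orientation that makes the step a de-noiser. A
bright voxel with zero bright neighbors gets ratio +∞ and is always
rejected. Out-of-bounds neighbors count as dark (conservative at borders).
The bright test is inclusive (`I ≥ 30`).

**Mean shift.** The kernel is applied per axis to squared normalized
offsets `u_i = (c − c_i)²/r²`, re-centered at their sphere mean with the
sphere standard deviation as bandwidth, and the new coordinate is the
kernel-weighted mean of raw coordinates. This per-axis composition is
implemented literally even though a conventional mean shift would use one
3D kernel; the intensity does not enter the kernel. `δ = 0` (all offsets
identical) degrades to uniform weights. Convergence is a first-step
displacement `< 0.5` voxel — the rounded voxel position does not change.
Basins are single-linkage clusters of final positions with a 1-voxel
cutoff; marks sharing a basin merge into one mark at the centroid of their
final positions, with the closest merged member dropped in its favor so
the mark/subordinate partition conserves the foreground count.
Trajectories that never converge within 100 steps are attached to the
nearest mark; if no voxel at all converges on its first step, the most
stationary member of each basin is promoted so downstream stages have
seeds. Node radii use the maximal-fitting-sphere rule: the largest integer
`s` with ≥ 99% foreground occupancy of the ball of radius `s`, floored at
1.0.

**Pruning.** The keep rule `D − (r₁ + r₂) > 3` is applied by a greedy
sweep in descending-radius order (ties: lexicographic coordinates), so
larger, more informative nodes win deterministically; no global covering
optimization is attempted. Subordinate sets are pruned independently —
cross-set overlaps are allowed by design.

**Sphere walk.** The two rotations are θ about X (aligning the chord's
YOZ projection with +Y) then γ about Z (aligning the once-rotated chord
with +Y′); the second angle is taken from the once-rotated terminal's
`(x₁, y₁)` components, the only reading under which the composition is a
well-defined rotation sending the terminal to `(0, D, 0)`. Only voxels
with `y′ > 0` (strictly forward) are candidates; quadrants are the four
sign combinations of `(x′, z′)`; empty quadrants score −∞; quadrant ties
break toward the lowest quadrant index. New centers must lie in the
binarized foreground mask (robust against background haze) rather than
merely having nonzero intensity. A visited-set guard forbids revisiting a
center (the formulation has no intrinsic anti-cycling rule); a forced
revisit, an empty forward hemisphere, or exhausting the step budget
`max(100, ⌈4·D/r⌉)` all end the walk as a failure, which is a normal
return value, not an error.

**Graph stage.** Pairs farther apart than the 40-voxel cutoff skip the
walk and take the penalty weight directly — the walk would exhaust its
budget anyway, and the cutoff bounds the O(n²) walker cost. Prim's
algorithm (natural for a dense weight table) with smallest-index
tie-breaking gives a deterministic tree; penalty edges are kept when the
MST needs them for connectivity, so an isolated segment is still attached
(and a genuine gap can still be bridged if no cheaper route exists — a
known limitation of the penalty formulation). The root defaults to the
largest-radius node (soma-like). Spur pruning is a simple iterative
deletion of leaf-to-branch segments shorter than 5 voxels — deliberately
simpler than signal-based hierarchical pruning schemes, since the step is
post-hoc cleanup rather than part of the reconstruction model.

**Difference scores.** Both trees are resampled at 1-voxel steps along
every parent–child segment; nearest-neighbor distances are computed in
both directions (KD-tree). ESA averages the two directional means; PDS
averages the two fractions above the 2-voxel visibility threshold; DSA is
the mean of all above-threshold distances (0 when none); MDNN is the
overall maximum. Distances are point-to-sample rather than
point-to-segment; with 1-voxel resampling the discrepancy is below half a
voxel. The bidirectional form makes all four scores symmetric.

## Synthetic phantoms

The generator emulates what fluorescence single-neuron stacks look like to
this pipeline: bright tubes (default intensity 200 on background 0, so the
default thresholds 30/0.3 are meaningful without tuning) with a linear
intensity falloff shell at the surface, branch points where tubes share
endpoints, gap boxes forced to zero, and isolated 255-intensity noise
voxels placed by seeded sampling at positions whose entire 26-neighborhood
is dark — isolated precisely so the binarization ratio test can be
asserted to remove them. Ground truth is the tube centerlines as SWC.
Rendering is deterministic given the seed.

The phantoms deliberately omit confocal PSF blur, depth attenuation,
anisotropic z-sampling and textured background. Passing tests on them
demonstrates the tracing logic (mode finding, gap handling, topology
recovery), not robustness to microscope physics; real stacks will stress
the binarization thresholds in ways these phantoms do not.

The `gap_vs_detour` phantom fixes the geometry at `|AB| = 8` across a
zeroed corridor and `|AC| = |CB| = 10` through solid tubes (the apex is at
`y = 6 + √84`, off the integer grid), so the adapted MST's detour
(10 + 10 ≈ 21) beats the penalized chord (100 · 8) while the Euclidean MST
prefers the chord. Problem sizes throughout the suite (volumes ≤ 48³,
hundreds of foreground voxels, ≤ 12 graph nodes) are chosen so each
pipeline stage's behavior is observable and exactly checkable against
brute-force oracles.

## Known limitations

- The per-axis kernel composition is followed literally; other mean-shift
  implementations of the same idea may differ in detail.
- Single tree per run: disconnected neurites are force-attached through
  penalty edges rather than returned as a forest.
- Low-intensity segments below the binarization thresholds are invisible
  to every later stage.
- The node-pruning threshold trades completeness against redundancy: too
  high deletes structure, too low keeps clutter.
- No topology-aware (DIADEM-style) scoring; the four scores are purely
  geometric.
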