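# amst — automatic 3D neuron tracing with an adapted minimum spanning tree

Reconstructing a neuron's morphology from a fluorescence image stack —
turning a 3D grid of intensities into an SWC tree of nodes with positions,
radii and parent links — is a core task in single-neuron informatics.
Spanning-tree tracers connect skeleton nodes by Euclidean distance, which
works until two distinct neurites pass close to each other across a genuine
gap in the signal: the nearest pair wins and the reconstruction bridges the
gap.

`amst` implements a tracing pipeline that fixes this by making edge weights
shape-aware:

1. **Binarization.** A voxel is *bright* if its intensity `I ≥ 30`, and
   *foreground* if additionally the dark/bright ratio over its 26 neighbors
   is ≤ 0.3 — a de-noising rule that discards isolated bright voxels.
2. **Mean-shift skeletonization.** Each foreground voxel is shifted to a
   weighted local mean inside a sphere of radius 5, iterated to convergence
   (≤ 100 steps). Per axis, offsets are converted to
   `u_i = (c − c_i)² / r²` and weighted by the Gaussian kernel
   `K(u) = (2πδ²)^{-1} exp(−C (u − ū)² / 2δ²)`, with `ū`, `δ` the mean and
   standard deviation of the converted offsets over the sphere. Voxels that
   cannot shift one step are *classification marks* (density modes along
   the skeleton); the rest become their *subordinates*.
3. **Covered-node pruning.** Nodes with radii overlap heavily; a pair is
   kept only when `D − (r₁ + r₂) > 3` voxels. Marks are pruned first, the
   removed marks' subordinates are remapped to their keepers through a
   two-level table, then each subordinate set is pruned the same way.
4. **Rotating-sphere pathways.** For each node pair (S, T) a sphere of
   radius 2 walks from S toward T. The frame is rotated (about X by θ, then
   about Z by γ) so the chord lies on +Y′; forward foreground voxels are
   split into 4 quadrants scored by the gravitation
   `F = (1/n) Σ cosθ · I₁I₂ / D²`, and the sphere steps to the best
   quadrant's voxel nearest T. Reaching T yields a pathway (node list); a
   dead end signals a gap.
5. **Adapted MST.** Edge weight `W_E = Σ Dis(p_i, p_{i+1})` along the
   pathway when one exists, else the penalty `W_E = M · Dis(S, T)` with
   `M = 100 > 10`. Prim's algorithm spans the nodes, chosen edges are
   filled in with their pathway nodes, and spurs shorter than 5 voxels are
   trimmed.

The package also provides the four reconstruction-difference scores used
to compare two SWC files — entire-structure average (ESA), different-
structure average (DSA), percentage of different structure (PDS) and max
distance of neurons' nodes (MDNN), all bidirectional nearest-neighbor
summaries on resampled trees — and a seeded synthetic-phantom generator
(tubes, branches, gaps, isolated noise) with known ground truth.

## Worked example

```sh
$ amst simulate --fixture y_branch -o yb.tif --truth yb_truth.swc
wrote y_branch volume (48, 44, 16) to yb.tif
wrote ground truth (37 records) to yb_truth.swc

$ amst trace yb.tif yb_traced.swc
INFO binarization: 132 foreground voxels (0.00s)
INFO mean shift: 6 marks, 132 nodes (0.04s)
INFO pruning: 12 nodes kept (0.00s)
INFO weight matrix: 58/66 pairs with pathways (0.08s)
INFO tree: 47 records after spur pruning
wrote 47 records to yb_traced.swc

$ amst compare yb_truth.swc yb_traced.swc
score  value (voxels)
ESA            0.4816
DSA            3.5492
PDS            0.0205
MDNN           4.4721
```

The phantom is a Y-shaped neurite (one trunk, two limbs). Binarization
keeps 132 voxels near the tube axes; mean shift collapses them onto 6 modes
plus subordinates, pruning thins those to 12 well-separated nodes, and the
adapted MST links them through sphere-walk pathways into a 47-record tree
with the correct topology (3 tips, 1 branch point). Against the ground
truth the traced tree deviates by about half a voxel on average (ESA 0.48)
and only 2% of the structure differs noticeably (PDS 0.02, threshold 2
voxels).

The same pipeline is available as a library:

```python
from amst import TraceConfig, read_volume, trace_volume
result = trace_volume(read_volume("yb.tif"), TraceConfig())
print(result.stage_counts)
```

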