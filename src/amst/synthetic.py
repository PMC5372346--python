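"""Synthetic fluorescence-style neuron phantoms with known ground truth.

Real single-neuron stacks are bright tubular segments of varying radius on
a dark background, with intensity falling off at tube edges, branch
points, scattered isolated bright voxels (shot noise), and occasional
signal drop-outs that leave gaps between segments.  The generator renders
exactly those features — tubes, gap boxes forced to zero, seeded isolated
noise voxels — and returns the tube centerlines as a ground-truth SWC
tree, so every pipeline stage is testable without any acquired data.

It does not simulate a confocal point-spread function, depth-dependent
attenuation or anisotropic z-sampling; conclusions drawn from phantoms
concern the tracing logic, not microscope physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import SWCRecord, SWCTree, Volume

__all__ = ["TubeSpec", "PhantomSpec", "render_phantom", "standard_fixtures"]


@dataclass
class TubeSpec:
    """A straight bright tube between two (possibly fractional) endpoints.

    ``falloff`` is the shell thickness (voxels) over which intensity decays
    linearly to 0 at the tube surface; 0 gives a hard-edged tube.
    """

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float = 2.0
    intensity: float = 200.0
    falloff: float = 1.0

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("tube radius must be >= 1")


@dataclass
class PhantomSpec:
    """Volume dims, tubes, zeroed gap boxes and isolated-voxel noise.

    ``gap_boxes`` are ((x0, x1), (y0, y1), (z0, z1)) inclusive voxel ranges
    forced to 0 after the tubes are rendered.  ``noise_rate`` is the
    expected fraction of volume voxels turned into isolated intensity-255
    spots; rendering is reproducible given ``seed``.
    """

    dims: tuple[int, int, int]
    tubes: list[TubeSpec] = field(default_factory=list)
    gap_boxes: list[tuple] = field(default_factory=list)
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for t in self.tubes:
            for p in (t.p0, t.p1):
                if not all(0 <= c < d for c, d in zip(p, self.dims)):
                    raise ValueError(f"tube endpoint {p} outside dims {self.dims}")


def _segment_distance(coords: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    v = p1 - p0
    vv = float(v @ v)
    if vv == 0:
        return np.linalg.norm(coords - p0, axis=-1)
    t = np.clip(((coords - p0) @ v) / vv, 0.0, 1.0)
    proj = p0 + t[..., None] * v
    return np.linalg.norm(coords - proj, axis=-1)


def render_phantom(spec: PhantomSpec) -> tuple[Volume, SWCTree]:
    """Render a phantom volume and its ground-truth centerline SWC.

    Overlapping tubes take the maximum intensity; gap boxes are zeroed
    after rendering; noise voxels are placed by seeded uniform sampling on
    background positions whose 26-neighborhood is also background, so each
    one is a genuinely isolated spot.
    """
    nx, ny, nz = spec.dims
    data = np.zeros(spec.dims, dtype=float)
    for tube in spec.tubes:
        p0 = np.asarray(tube.p0, dtype=float)
        p1 = np.asarray(tube.p1, dtype=float)
        r = tube.radius
        lo = np.maximum(np.floor(np.minimum(p0, p1) - r - 1).astype(int), 0)
        hi = np.minimum(np.ceil(np.maximum(p0, p1) + r + 1).astype(int) + 1, spec.dims)
        xs, ys, zs = (np.arange(lo[i], hi[i]) for i in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        coords = np.stack([gx, gy, gz], axis=-1).astype(float)
        d = _segment_distance(coords, p0, p1)
        if tube.falloff > 0:
            profile = np.clip((r - d) / tube.falloff, 0.0, 1.0)
        else:
            profile = (d <= r).astype(float)
        block = data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        np.maximum(block, tube.intensity * profile, out=block)
    for (x0, x1), (y0, y1), (z0, z1) in spec.gap_boxes:
        data[x0 : x1 + 1, y0 : y1 + 1, z0 : z1 + 1] = 0.0

    data = np.rint(np.clip(data, 0, 255)).astype(np.uint8)

    if spec.noise_rate > 0:
        rng = np.random.default_rng(spec.seed)
        n_target = int(round(spec.noise_rate * data.size))
        placed = 0
        attempts = 0
        while placed < n_target and attempts < 50 * max(n_target, 1):
            attempts += 1
            p = rng.integers(1, [nx - 1, ny - 1, nz - 1])
            block = data[p[0] - 1 : p[0] + 2, p[1] - 1 : p[1] + 2, p[2] - 1 : p[2] + 2]
            if block.max() == 0:  # voxel and all 26 neighbors dark
                data[tuple(p)] = 255
                placed += 1

    return Volume(data), _truth_tree(spec)


def _truth_tree(spec: PhantomSpec, step: float = 2.0) -> SWCTree:
    """Tube centerlines as an SWC tree; shared endpoints become junctions."""
    if not spec.tubes:
        return SWCTree([])
    points: list[np.ndarray] = []
    radii: list[float] = []
    edges: list[tuple[int, int]] = []

    def add_point(p: np.ndarray, r: float) -> int:
        for i, q in enumerate(points):
            if np.linalg.norm(q - p) < 0.5:
                return i
        points.append(p)
        radii.append(max(1.0, r))
        return len(points) - 1

    for tube in spec.tubes:
        p0 = np.asarray(tube.p0, dtype=float)
        p1 = np.asarray(tube.p1, dtype=float)
        length = float(np.linalg.norm(p1 - p0))
        nseg = max(1, int(np.ceil(length / step)))
        prev = add_point(p0, tube.radius)
        for k in range(1, nseg + 1):
            cur = add_point(p0 + (p1 - p0) * (k / nseg), tube.radius)
            if cur != prev:
                edges.append((prev, cur))
            prev = cur

    # spanning forest by BFS over the junction-merged polyline graph
    adj: dict[int, list[int]] = {i: [] for i in range(len(points))}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    parent: dict[int, int | None] = {}
    for root in range(len(points)):
        if root in parent:
            continue
        parent[root] = None
        queue = [root]
        while queue:
            u = queue.pop(0)
            for v in adj[u]:
                if v not in parent:
                    parent[v] = u
                    queue.append(v)

    records = []
    for i, p in enumerate(points):
        par = parent[i]
        records.append(
            SWCRecord(
                id=i + 1,
                type_code=1 if par is None else 3,
                x=float(p[0]),
                y=float(p[1]),
                z=float(p[2]),
                radius=radii[i],
                parent=-1 if par is None else par + 1,
            )
        )
    tree = SWCTree(records)
    tree.validate()
    return tree


def standard_fixtures(seed: int = 0) -> dict[str, PhantomSpec]:
    """The named phantoms used throughout the test suite.

    * ``straight_tube`` — one axis-aligned tube, radius 2, length 30.
    * ``y_branch`` — a trunk splitting into two limbs; three tips, one
      branch point in the ground truth.
    * ``gap_pair`` — two collinear stubs separated by a 6-voxel zeroed gap
      (wider than one sphere diameter, so the walker must fail).
    * ``gap_vs_detour`` — nodes A and B 8 voxels apart across a gap, with a
      solid tube detour A-C-B of 10 + 10 voxels: the adapted MST should
      route around, a Euclidean MST straight across.
    * ``noisy_tube`` — the straight tube plus isolated bright noise voxels.
    * ``ball`` / ``two_balls`` — solid uniform spheres (radius 3) for
      mean-shift centroid recovery; the two-ball centers are 30 voxels
      apart.
    """
    sq84 = float(np.sqrt(84.0))  # detour apex height: |AC| = |CB| = 10 with |AB| = 8
    return {
        "straight_tube": PhantomSpec(
            dims=(40, 16, 16),
            tubes=[TubeSpec(p0=(5, 8, 8), p1=(35, 8, 8), radius=2, falloff=0.5)],
            seed=seed,
        ),
        "y_branch": PhantomSpec(
            dims=(48, 44, 16),
            tubes=[
                TubeSpec(p0=(4, 22, 8), p1=(24, 22, 8), radius=2, falloff=0.5),
                TubeSpec(p0=(24, 22, 8), p1=(44, 36, 8), radius=2, falloff=0.5),
                TubeSpec(p0=(24, 22, 8), p1=(44, 8, 8), radius=2, falloff=0.5),
            ],
            seed=seed,
        ),
        "gap_pair": PhantomSpec(
            dims=(40, 16, 16),
            tubes=[
                TubeSpec(p0=(4, 8, 8), p1=(16, 8, 8), radius=2, falloff=0.5),
                TubeSpec(p0=(24, 8, 8), p1=(36, 8, 8), radius=2, falloff=0.5),
            ],
            gap_boxes=[((17, 23), (0, 15), (0, 15))],
            seed=seed,
        ),
        "gap_vs_detour": PhantomSpec(
            dims=(32, 28, 16),
            tubes=[
                TubeSpec(p0=(10, 6, 8), p1=(14, 6 + sq84, 8), radius=2, falloff=0.5),
                TubeSpec(p0=(14, 6 + sq84, 8), p1=(18, 6, 8), radius=2, falloff=0.5),
            ],
            # zero the direct chord corridor between A=(10,6,8) and B=(18,6,8)
            gap_boxes=[((12, 16), (0, 8), (0, 15))],
            seed=seed,
        ),
        "noisy_tube": PhantomSpec(
            dims=(40, 16, 16),
            tubes=[TubeSpec(p0=(5, 8, 8), p1=(35, 8, 8), radius=2, falloff=0.5)],
            noise_rate=3e-4,
            seed=seed,
        ),
        "ball": PhantomSpec(
            dims=(16, 16, 16),
            tubes=[TubeSpec(p0=(8, 8, 8), p1=(8, 8, 8), radius=3, falloff=0.0)],
            seed=seed,
        ),
        "two_balls": PhantomSpec(
            dims=(46, 16, 16),
            tubes=[
                TubeSpec(p0=(8, 8, 8), p1=(8, 8, 8), radius=3, falloff=0.0),
                TubeSpec(p0=(38, 8, 8), p1=(38, 8, 8), radius=3, falloff=0.0),
            ],
            seed=seed,
        ),
    }
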