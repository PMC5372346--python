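"""Mean-shift skeletonization of the foreground voxel cloud.

Every foreground voxel is shifted iteratively to a weighted local mean of
the foreground voxels inside a sphere around it.  Voxels that do not move on
their first shift are *classification marks* (density modes, which on a
tubular foreground line up along the neuron skeleton); every other voxel is
*subordinated* to the mark whose convergence basin its trajectory lands in.

The per-axis shift uses a Gaussian kernel over *converted offsets*: for axis
x and sphere radius r the offset of voxel i from the center c is converted
to ``u_i = (c_x - x_i)^2 / r^2``; the kernel is centered at the mean
converted offset over the sphere and scaled by their standard deviation, and
the new center coordinate is the kernel-weighted average of the raw voxel
coordinates.  The y and z axes are treated identically and independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binarize import ForegroundMask
from .volume_io import Volume

__all__ = [
    "MeanShiftParams",
    "Node",
    "MarkTable",
    "LostVoxel",
    "kernel_weight",
    "shift_once",
    "run_mean_shift",
    "estimate_radius",
]


@dataclass
class MeanShiftParams:
    """Mean-shift configuration.

    kernel_scale : scaling coefficient C inside the Gaussian exponent
        (dimensionless, default 1.0).
    sphere_radius : radius r of the local sphere, voxels (default 5).
    max_iterations : cap on shifts per voxel to avoid endless loops
        (default 100).
    convergence_tol : displacement below which a shift counts as "cannot
        shift for one step" (voxels, default 0.5 — the rounded voxel
        position is unchanged).
    """

    kernel_scale: float = 1.0
    sphere_radius: float = 5.0
    max_iterations: int = 100
    convergence_tol: float = 0.5

    def __post_init__(self) -> None:
        if self.sphere_radius < 1:
            raise ValueError("sphere_radius must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")


@dataclass
class Node:
    """A skeleton node: position (fractional voxels), radius, intensity."""

    x: float
    y: float
    z: float
    radius: float = 1.0
    intensity: float = 0.0

    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def distance_to(self, other: "Node") -> float:
        return float(np.linalg.norm(self.position() - other.position()))


@dataclass
class MarkTable:
    """Classification marks and the voxels subordinated to each of them."""

    marks: list[Node] = field(default_factory=list)
    subordinates: dict[int, list[Node]] = field(default_factory=dict)

    def total_nodes(self) -> int:
        return len(self.marks) + sum(len(v) for v in self.subordinates.values())


class LostVoxel(Exception):
    """Raised when a shift sphere contains no foreground voxel."""


def kernel_weight(u, u_mean: float, delta: float, C: float = 1.0):
    """Gaussian kernel weight for a converted offset ``u``.

    ``K(u) = 1/(2 pi delta^2) * exp(-C (u - u_mean)^2 / (2 delta^2))`` where
    ``u_mean`` is the mean converted offset over the sphere and ``delta``
    their standard deviation.  A zero ``delta`` means all offsets are
    identical; the weight is then uniform (1).
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    u = np.asarray(u, dtype=float)
    if delta == 0:
        return np.ones_like(u)
    return (1.0 / (2.0 * np.pi * delta**2)) * np.exp(
        -C * (u - u_mean) ** 2 / (2.0 * delta**2)
    )


def _sphere_foreground(mask: np.ndarray, center: np.ndarray, r: float) -> np.ndarray:
    """(n, 3) coordinates of foreground voxels within Euclidean r of center."""
    dims = mask.shape
    lo = np.maximum(np.floor(center - r).astype(int), 0)
    hi = np.minimum(np.ceil(center + r).astype(int) + 1, dims)
    if np.any(lo >= hi):
        return np.empty((0, 3), dtype=int)
    sub = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    coords = np.argwhere(sub) + lo
    if coords.size == 0:
        return coords.reshape(0, 3)
    d2 = np.sum((coords - center) ** 2, axis=1)
    return coords[d2 <= r * r + 1e-12]


def shift_once(
    mask: ForegroundMask, center, params: MeanShiftParams | None = None
) -> np.ndarray:
    """One mean-shift step of a sphere center; per-axis weighted average.

    Raises :class:`LostVoxel` if the sphere holds no foreground voxel.  The
    result is a convex combination of foreground voxel coordinates, so it
    never leaves their bounding box.
    """
    params = params or MeanShiftParams()
    center = np.asarray(center, dtype=float)
    pts = _sphere_foreground(mask.mask, center, params.sphere_radius)
    if len(pts) == 0:
        raise LostVoxel(f"no foreground voxel within {params.sphere_radius} of {center}")
    r2 = params.sphere_radius**2
    new = np.empty(3)
    for ax in range(3):
        raw = pts[:, ax].astype(float)
        u = (center[ax] - raw) ** 2 / r2
        u_mean = float(u.mean())
        delta = float(u.std())
        w = kernel_weight(u, u_mean, delta, params.kernel_scale)
        new[ax] = float(np.sum(w * raw) / np.sum(w))
    return new


def _merge_clusters(finals: np.ndarray, tol: float = 1.0) -> np.ndarray:
    """Single-linkage clustering of final positions with cutoff ``tol``.

    Returns a label per row.  Transitive closure via union-find over all
    pairs closer than ``tol``.
    """
    from scipy.spatial import cKDTree

    n = len(finals)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(finals)
    for i, j in tree.query_pairs(tol):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    return np.array([find(i) for i in range(n)])


def run_mean_shift(
    vol: Volume, mask: ForegroundMask, params: MeanShiftParams | None = None
) -> MarkTable:
    """Shift every foreground voxel to convergence and build the mark table.

    A voxel whose first shift moves it less than ``convergence_tol`` is a
    mark; trajectories are followed until their step falls below the
    tolerance or ``max_iterations`` is reached.  Final positions within 1
    voxel of each other (transitively) form one basin: marks in a shared
    basin merge into a single mark, and every non-mark voxel in the basin is
    subordinated to it.  Basins containing no mark are attached to the
    nearest mark by final position.
    """
    params = params or MeanShiftParams()
    coords = mask.coordinates().astype(float)
    if len(coords) == 0:
        return MarkTable()

    finals = np.empty_like(coords)
    first_disp = np.empty(len(coords))
    lost = np.zeros(len(coords), dtype=bool)
    for k, start in enumerate(coords):
        pos = start.copy()
        try:
            for it in range(params.max_iterations):
                new = shift_once(mask, pos, params)
                disp = float(np.linalg.norm(new - pos))
                if it == 0:
                    first_disp[k] = disp
                pos = new
                if disp < params.convergence_tol:
                    break
        except LostVoxel:
            lost[k] = True
            first_disp[k] = np.inf
        finals[k] = pos

    keep = ~lost
    coords, finals, first_disp = coords[keep], finals[keep], first_disp[keep]
    if len(coords) == 0:
        return MarkTable()
    is_mark = first_disp < params.convergence_tol

    labels = _merge_clusters(finals, tol=1.0)
    table = MarkTable()
    mark_positions: list[np.ndarray] = []
    pending: list[np.ndarray] = []  # member original coords of markless basins
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        mark_members = members[is_mark[members]]
        if len(mark_members) == 0:
            pending.append(members)
            continue
        # merged mark: centroid of the final positions of converged members;
        # every basin member (including merged-away marks) stays in the
        # table as a subordinate so no foreground voxel is lost
        mpos = finals[mark_members].mean(axis=0)
        idx = len(table.marks)
        table.marks.append(_make_node(mpos, vol, mask))
        mark_positions.append(mpos)
        rep = mark_members[
            int(np.argmin(np.sum((finals[mark_members] - mpos) ** 2, axis=1)))
        ]
        table.subordinates[idx] = [
            _make_node(coords[i], vol, mask) for i in members if i != rep
        ]

    if pending and not table.marks:
        # no voxel converged on its first shift anywhere: promote the most
        # stationary member of each basin so downstream stages have seeds
        for members in pending:
            best = members[np.argmin(first_disp[members])]
            idx = len(table.marks)
            table.marks.append(_make_node(coords[best], vol, mask))
            mark_positions.append(coords[best])
            table.subordinates[idx] = [
                _make_node(coords[i], vol, mask) for i in members if i != best
            ]
    elif pending:
        mp = np.array(mark_positions)
        for members in pending:
            centroid = finals[members].mean(axis=0)
            idx = int(np.argmin(np.sum((mp - centroid) ** 2, axis=1)))
            table.subordinates[idx].extend(
                _make_node(coords[i], vol, mask) for i in members
            )
    return table


def _make_node(pos: np.ndarray, vol: Volume, mask: ForegroundMask) -> Node:
    return Node(
        x=float(pos[0]),
        y=float(pos[1]),
        z=float(pos[2]),
        radius=estimate_radius(mask, pos),
        intensity=float(vol.intensity_at(pos)),
    )


def estimate_radius(mask: ForegroundMask, point, occupancy: float = 0.99) -> float:
    """Maximal-fitting-sphere radius at a point.

    The radius is the largest integer ``s >= 1`` such that at least
    ``occupancy`` (99%) of the voxels within Euclidean distance ``s`` of the
    point are foreground, floored at 1.0.  On background the test fails at
    s = 1 and the minimum 1.0 is returned.  Monotone non-increasing as the
    foreground shrinks.
    """
    point = np.asarray(point, dtype=float)
    m = mask.mask
    dims = np.array(m.shape)
    best = 1.0
    s = 1
    max_s = int(np.ceil(dims.max()))
    while s <= max_s:
        lo = np.floor(point - s).astype(int)
        hi = np.ceil(point + s).astype(int) + 1
        xs = np.arange(lo[0], hi[0])
        ys = np.arange(lo[1], hi[1])
        zs = np.arange(lo[2], hi[2])
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        d2 = (gx - point[0]) ** 2 + (gy - point[1]) ** 2 + (gz - point[2]) ** 2
        inside = d2 <= s * s + 1e-12
        gxi, gyi, gzi = gx[inside], gy[inside], gz[inside]
        inb = (
            (gxi >= 0)
            & (gxi < dims[0])
            & (gyi >= 0)
            & (gyi < dims[1])
            & (gzi >= 0)
            & (gzi < dims[2])
        )
        total = int(inside.sum())
        fg = int(m[gxi[inb], gyi[inb], gzi[inb]].sum())  # out-of-bounds = background
        if total == 0 or fg / total < occupancy:
            break
        best = float(s)
        s += 1
    return best
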