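"""Pathway extraction with a rotating sphere.

A small sphere is walked from a starting node toward a terminal node
through foreground voxels.  At every step the coordinate frame is rotated
in two stages so the chord to the terminal lies along the positive Y' axis:
first about X (angle theta) to bring the terminal's YOZ-plane projection
onto +Y, then about Z (angle gamma) to bring the once-rotated terminal onto
+Y'.  Foreground voxels in the forward hemisphere (y' > 0) are binned into
four quadrants by the signs of (x', z'); each quadrant scores a
"gravitation" toward the terminal,

    F = (1/n) * sum_i cos(theta_i) * I_1,i * I_2 / D_i^2,

with theta_i the angle of voxel i off the +Y' axis, I_1 the voxel
intensity, I_2 the terminal intensity, D_i the voxel-terminal distance and
n the quadrant occupancy.  The sphere moves to the best quadrant's voxel
nearest the terminal and repeats until the terminal falls within the
sphere.  A walk fails — signalling a gap — when no forward foreground voxel
exists, when a center would repeat, or when the step budget is exhausted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .binarize import ForegroundMask
from .meanshift import Node
from .volume_io import Volume

__all__ = [
    "RotationFrame",
    "WalkParams",
    "Pathway",
    "QuadrantStat",
    "rotation_frame",
    "rotate_point",
    "quadrant_scores",
    "extract_pathway",
]


@dataclass
class RotationFrame:
    """Two-stage rotation taking the chord (terminal - origin) to +Y'."""

    theta: float  # about X
    gamma: float  # about Z
    origin: np.ndarray

    def matrix(self) -> np.ndarray:
        ct, st = math.cos(self.theta), math.sin(self.theta)
        cg, sg = math.cos(self.gamma), math.sin(self.gamma)
        rx = np.array([[1, 0, 0], [0, ct, -st], [0, st, ct]])
        rz = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
        return rz @ rx


@dataclass
class WalkParams:
    """sphere_radius (default 2 voxels), 4 quadrants, and a step budget.

    ``max_steps`` of None resolves per pair to max(100, ceil(4 D / radius)).
    """

    sphere_radius: float = 2.0
    n_quadrants: int = 4
    max_steps: int | None = None

    def __post_init__(self) -> None:
        if self.sphere_radius < 1:
            raise ValueError("sphere_radius must be >= 1")
        if self.n_quadrants != 4:
            raise ValueError("the sphere is split into 4 quadrants")

    def resolve_max_steps(self, chord: float) -> int:
        if self.max_steps is not None:
            return self.max_steps
        return max(100, math.ceil(4.0 * chord / self.sphere_radius))


@dataclass
class Pathway:
    """Ordered chain of sphere centers from start to terminal."""

    nodes: list[np.ndarray] = field(default_factory=list)
    length: float = 0.0
    success: bool = False


@dataclass
class QuadrantStat:
    F: float
    n: int
    best_voxel: np.ndarray | None


def rotation_frame(start, terminal) -> RotationFrame:
    """Build the two-stage rotation for a start/terminal pair.

    theta rotates about X so the terminal's projection onto the YOZ plane
    lands on +Y; gamma rotates about Z so the once-rotated terminal lands on
    +Y'.  The composition maps the terminal to (0, D, 0).
    """
    start = np.asarray(start, dtype=float)
    terminal = np.asarray(terminal, dtype=float)
    v = terminal - start
    d = float(np.linalg.norm(v))
    if d == 0:
        raise ValueError("degenerate frame: start == terminal")
    x, y, z = v
    theta = math.atan2(-z, y) if (y != 0 or z != 0) else 0.0
    h = math.hypot(y, z)
    gamma = math.atan2(x, h)
    return RotationFrame(theta=theta, gamma=gamma, origin=start)


def rotate_point(p, frame: RotationFrame) -> np.ndarray:
    """Apply the frame's X-rotation then Z-rotation to ``p - origin``."""
    return frame.matrix() @ (np.asarray(p, dtype=float) - frame.origin)


def _sphere_voxels(mask: np.ndarray, center: np.ndarray, r: float) -> np.ndarray:
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


def quadrant_scores(
    vol: Volume,
    mask: ForegroundMask,
    frame: RotationFrame,
    terminal: Node,
    params: WalkParams | None = None,
) -> list[QuadrantStat]:
    """Score the four forward quadrants of the sphere at ``frame.origin``.

    Only foreground voxels with rotated y' > 0 participate (the backward
    hemisphere has negative cosine and is never a candidate).  Empty
    quadrants score -inf.
    """
    params = params or WalkParams()
    tpos = terminal.position()
    voxels = _sphere_voxels(mask.mask, frame.origin, params.sphere_radius)
    stats = [QuadrantStat(F=-np.inf, n=0, best_voxel=None) for _ in range(4)]
    if len(voxels) == 0:
        return stats
    rot = (frame.matrix() @ (voxels.astype(float) - frame.origin).T).T
    forward = rot[:, 1] > 1e-12
    voxels, rot = voxels[forward], rot[forward]
    if len(voxels) == 0:
        return stats
    norms = np.linalg.norm(rot, axis=1)
    cos_theta = rot[:, 1] / norms
    d_term = np.linalg.norm(voxels - tpos, axis=1)
    d_term = np.maximum(d_term, 1e-9)
    i1 = vol.data[voxels[:, 0], voxels[:, 1], voxels[:, 2]].astype(float)
    i2 = float(terminal.intensity)
    contrib = cos_theta * (i1 * i2) / d_term**2
    quad = (rot[:, 0] < 0).astype(int) + 2 * (rot[:, 2] < 0).astype(int)
    for q in range(4):
        sel = quad == q
        n = int(sel.sum())
        if n == 0:
            continue
        best = voxels[sel][np.argmin(d_term[sel])]
        stats[q] = QuadrantStat(F=float(contrib[sel].sum() / n), n=n, best_voxel=best)
    return stats


def extract_pathway(
    vol: Volume,
    mask: ForegroundMask,
    start: Node,
    terminal: Node,
    params: WalkParams | None = None,
) -> Pathway:
    """Walk the sphere from ``start`` toward ``terminal``.

    Returns a :class:`Pathway`; failure (gap, forced revisit or step budget
    exhausted) is a normal return with ``success=False``, not an exception.
    On success the terminal is the last node and consecutive nodes are at
    most one sphere diameter apart.
    """
    params = params or WalkParams()
    spos, tpos = start.position(), terminal.position()
    chord = float(np.linalg.norm(tpos - spos))
    nodes = [spos]
    if chord <= params.sphere_radius:
        nodes.append(tpos)
        return Pathway(nodes=nodes, length=chord, success=True)

    budget = params.resolve_max_steps(chord)
    visited: set[tuple[float, float, float]] = {tuple(np.round(spos, 6))}
    center = spos
    length = 0.0
    for _ in range(budget):
        frame = rotation_frame(center, tpos)
        stats = quadrant_scores(vol, mask, frame, terminal, params)
        best_q = max(range(4), key=lambda q: (stats[q].F, -q))
        if not np.isfinite(stats[best_q].F):
            return Pathway(nodes=nodes, length=length, success=False)  # gap
        new_center = stats[best_q].best_voxel.astype(float)
        key = tuple(np.round(new_center, 6))
        if key in visited:
            return Pathway(nodes=nodes, length=length, success=False)
        visited.add(key)
        length += float(np.linalg.norm(new_center - center))
        center = new_center
        nodes.append(center)
        if float(np.linalg.norm(tpos - center)) <= params.sphere_radius:
            length += float(np.linalg.norm(tpos - center))
            nodes.append(tpos)
            return Pathway(nodes=nodes, length=length, success=True)
    return Pathway(nodes=nodes, length=length, success=False)
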