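"""Adapted-weight minimum spanning tree reconstruction.

The classic spatial-distance MST connects whichever nodes are closest,
which happily bridges genuine gaps between different neuron segments.  The
adapted weight replaces the Euclidean distance with the accumulated length
of the sphere-walk pathway between a pair when one exists, and with a large
penalty ``M * Dis(S, T)`` (M > 10) when the walk fails — a failed walk is
evidence of a gap, so gap-crossing edges become expensive and the MST
routes through solid foreground instead.  Chosen edges are then expanded
("filled in") with their pathway's intermediate nodes, and short spurs are
trimmed from the final tree.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np

from .binarize import ForegroundMask
from .meanshift import Node, estimate_radius
from .sphere_path import Pathway, WalkParams, extract_pathway
from .volume_io import SWCRecord, SWCTree, Volume

__all__ = [
    "WeightParams",
    "WeightMatrix",
    "edge_weight",
    "build_weight_matrix",
    "euclidean_weight_matrix",
    "minimum_spanning_tree",
    "assemble_tree",
    "prune_spurs",
]


@dataclass
class WeightParams:
    """M: gap-penalty multiplier (> 10, default 100); pair_cutoff: pairs
    farther apart than this (voxels, default 40) skip the sphere walk and
    take the penalty weight directly — the walk would exhaust its step
    budget anyway."""

    M: int = 100
    pair_cutoff: float = 40.0

    def __post_init__(self) -> None:
        if self.M <= 10:
            raise ValueError("M must be a positive integer greater than 10")


@dataclass
class WeightMatrix:
    """Symmetric all-pairs weight table with per-pair stored pathways."""

    weights: np.ndarray
    pathways: dict[tuple[int, int], Pathway] = field(default_factory=dict)

    def pathway(self, i: int, j: int) -> Pathway | None:
        return self.pathways.get((min(i, j), max(i, j)))


def edge_weight(
    path: Pathway, start: Node, terminal: Node, params: WeightParams | None = None
) -> float:
    """Adapted edge weight for one node pair.

    Successful pathway: the accumulated Euclidean distance along its node
    list.  Failure: ``M * Dis(start, terminal)``.
    """
    params = params or WeightParams()
    if path.success:
        pts = np.asarray(path.nodes)
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    return params.M * start.distance_to(terminal)


def build_weight_matrix(
    nodes: list[Node],
    vol: Volume,
    mask: ForegroundMask,
    wparams: WeightParams | None = None,
    walkparams: WalkParams | None = None,
) -> WeightMatrix:
    """Run the sphere walk for every in-range pair and assemble W_E.

    The matrix is symmetric with a zero diagonal and every entry is at
    least the pair's Euclidean distance (pathway lengths by the triangle
    inequality, penalties because M > 10).
    """
    wparams = wparams or WeightParams()
    walkparams = walkparams or WalkParams()
    n = len(nodes)
    w = np.zeros((n, n))
    mat = WeightMatrix(weights=w)
    for i, j in itertools.combinations(range(n), 2):
        dist = nodes[i].distance_to(nodes[j])
        if dist > wparams.pair_cutoff:
            w[i, j] = w[j, i] = wparams.M * dist
            continue
        path = extract_pathway(vol, mask, nodes[i], nodes[j], walkparams)
        w[i, j] = w[j, i] = edge_weight(path, nodes[i], nodes[j], wparams)
        if path.success:
            mat.pathways[(i, j)] = path
    return mat


def euclidean_weight_matrix(nodes: list[Node]) -> WeightMatrix:
    """Plain spatial-distance weights (the unadapted baseline)."""
    pos = np.array([nd.position() for nd in nodes])
    diff = pos[:, None, :] - pos[None, :, :]
    return WeightMatrix(weights=np.linalg.norm(diff, axis=2))


def minimum_spanning_tree(w: WeightMatrix, root: int = 0) -> dict[int, int | None]:
    """Prim's algorithm on the dense weight table.

    Returns a parent map (root maps to None).  Ties are broken toward the
    smallest node index so the result is deterministic.
    """
    n = len(w.weights)
    if n == 0:
        return {}
    parents: dict[int, int | None] = {root: None}
    best: list[tuple[float, int, int]] = []
    in_tree = {root}

    def push(u: int) -> None:
        for v in range(n):
            if v not in in_tree:
                heapq.heappush(best, (float(w.weights[u, v]), v, u))

    push(root)
    while len(in_tree) < n and best:
        wt, v, u = heapq.heappop(best)
        if v in in_tree:
            continue
        parents[v] = u
        in_tree.add(v)
        push(v)
    return parents


def assemble_tree(
    parents: dict[int, int | None],
    w: WeightMatrix,
    nodes: list[Node],
    vol: Volume | None = None,
    mask: ForegroundMask | None = None,
) -> SWCTree:
    """Expand MST edges into SWC records, filling pathways back in.

    Each chosen edge with a stored successful pathway contributes its
    intermediate sphere centers as extra records chained between the two
    endpoints; edges without one become direct parent links.  Intermediate
    radii come from the maximal-fitting-sphere estimate when a mask is
    given, else 1.0.
    """
    order = _topological(parents)
    records: list[SWCRecord] = []
    next_id = 1
    id_of: dict[int, int] = {}
    for v in order:
        u = parents[v]
        node = nodes[v]
        if u is None:
            records.append(_record(next_id, node, parent=-1))
            id_of[v] = next_id
            next_id += 1
            continue
        path = w.pathway(u, v)
        parent_id = id_of[u]
        if path is not None:
            pts = path.nodes
            # orient from parent u toward child v
            if np.linalg.norm(pts[0] - nodes[u].position()) > np.linalg.norm(
                pts[-1] - nodes[u].position()
            ):
                pts = pts[::-1]
            for p in pts[1:-1]:
                rad = estimate_radius(mask, p) if mask is not None else 1.0
                inten = vol.intensity_at(p) if vol is not None else 0.0
                records.append(
                    SWCRecord(
                        id=next_id,
                        type_code=3,
                        x=float(p[0]),
                        y=float(p[1]),
                        z=float(p[2]),
                        radius=rad,
                        parent=parent_id,
                    )
                )
                parent_id = next_id
                next_id += 1
        records.append(_record(next_id, node, parent=parent_id))
        id_of[v] = next_id
        next_id += 1
    tree = SWCTree(records)
    tree.validate()
    return tree


def _record(rid: int, node: Node, parent: int) -> SWCRecord:
    type_code = 1 if parent == -1 else 3
    return SWCRecord(
        id=rid,
        type_code=type_code,
        x=node.x,
        y=node.y,
        z=node.z,
        radius=max(1.0, node.radius),
        parent=parent,
    )


def _topological(parents: dict[int, int | None]) -> list[int]:
    children: dict[int, list[int]] = {v: [] for v in parents}
    roots = []
    for v, u in parents.items():
        if u is None:
            roots.append(v)
        else:
            children[u].append(v)
    order: list[int] = []
    stack = list(reversed(sorted(roots)))
    seen: set[int] = set()
    while stack:
        v = stack.pop()
        if v in seen:
            raise ValueError("cycle in parent map")
        seen.add(v)
        order.append(v)
        stack.extend(sorted(children[v], reverse=True))
    if len(order) != len(parents):
        raise ValueError("cycle in parent map")
    return order


def prune_spurs(tree: SWCTree, min_spur_length: float = 5.0) -> SWCTree:
    """Iteratively delete leaf-to-branch segments shorter than the cutoff.

    A spur is the chain from a leaf up to (but excluding) the nearest
    branch point or root; spurs whose path length is below
    ``min_spur_length`` are removed until no such spur remains.  The root
    always survives.  Idempotent by construction.
    """
    records = {r.id: r for r in tree.records}
    changed = True
    while changed:
        changed = False
        kids: dict[int, list[int]] = {rid: [] for rid in records}
        for r in records.values():
            if r.parent != -1 and r.parent in kids:
                kids[r.parent].append(r.id)
        leaves = [rid for rid, ks in kids.items() if not ks]
        for leaf in leaves:
            if leaf not in records:
                continue
            chain = []
            cur = leaf
            length = 0.0
            while True:
                r = records[cur]
                if r.parent == -1 or len(kids[r.parent]) > 1:
                    break
                chain.append(cur)
                length += float(
                    np.linalg.norm(r.position() - records[r.parent].position())
                )
                cur = r.parent
            if cur == leaf and records[leaf].parent != -1:
                # leaf directly under a branch point: single-edge spur
                chain = [leaf]
                length = float(
                    np.linalg.norm(
                        records[leaf].position()
                        - records[records[leaf].parent].position()
                    )
                )
            if chain and length < min_spur_length:
                for rid in chain:
                    records.pop(rid, None)
                changed = True
    ordered = [r for r in tree.records if r.id in records]
    out = SWCTree(ordered)
    out.validate()
    return out
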