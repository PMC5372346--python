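"""Covered-node pruning.

After radii are attached, many skeleton nodes overlap or are covered by
their neighbors; the morphology should be expressed with as few nodes as
possible.  Pruning runs in three passes: (1) covered marks are removed by a
greedy sweep, (2) each removed mark is demoted to an ordinary node and it
and its subordinates are re-subordinated to the mark that covers it (the
two-level remap table), (3) within every subordinate set the same sweep
removes covered subordinates while the mark itself always survives.

Two nodes are both kept when the difference between their Euclidean
distance and the sum of their radii exceeds the cover threshold (default 3
voxels — the scale above which the eye can tell detail apart).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .meanshift import MarkTable, Node

__all__ = [
    "PruneParams",
    "RemapTable",
    "keep_pair",
    "prune_marks",
    "remark_subordinates",
    "prune_subordinates",
    "prune_mark_table",
]


@dataclass
class PruneParams:
    """cover_threshold: minimum clearance D - (r_a + r_b), voxels (default 3)."""

    cover_threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.cover_threshold < 0:
            raise ValueError("cover_threshold must be >= 0")


@dataclass
class RemapTable:
    """keeper mark index -> {removed mark index -> its subordinate nodes}."""

    table: dict[int, dict[int, list[Node]]] = field(default_factory=dict)

    def removed_indices(self) -> set[int]:
        return {ri for inner in self.table.values() for ri in inner}


def keep_pair(a: Node, b: Node, params: PruneParams | None = None) -> bool:
    """True iff both nodes are kept: D(a, b) - (r_a + r_b) > cover_threshold."""
    params = params or PruneParams()
    return a.distance_to(b) - (a.radius + b.radius) > params.cover_threshold


def _sweep_order(nodes: list[Node], indices: list[int]) -> list[int]:
    # descending radius; ties broken lexicographically on coordinates
    return sorted(
        indices,
        key=lambda i: (-nodes[i].radius, nodes[i].x, nodes[i].y, nodes[i].z),
    )


def prune_marks(
    marks: list[Node], params: PruneParams | None = None
) -> tuple[list[int], RemapTable]:
    """Greedy keep-sweep over marks in descending-radius order.

    Returns the kept mark indices (into ``marks``) and the remap table
    recording, for each removed mark, the kept mark that covers it.  All
    surviving pairs satisfy :func:`keep_pair`.
    """
    params = params or PruneParams()
    kept: list[int] = []
    remap = RemapTable()
    for i in _sweep_order(marks, list(range(len(marks)))):
        coverer = next((k for k in kept if not keep_pair(marks[i], marks[k], params)), None)
        if coverer is None:
            kept.append(i)
        else:
            remap.table.setdefault(coverer, {})[i] = []
    return sorted(kept), remap


def remark_subordinates(remap: RemapTable, table: MarkTable) -> MarkTable:
    """Fold removed marks and their subordinates into their keepers.

    Each removed mark becomes an ordinary node appended, together with its
    whole subordinate list, to its keeper's subordinate set.  The total node
    count is conserved.
    """
    removed = remap.removed_indices()
    kept = [i for i in range(len(table.marks)) if i not in removed]
    new = MarkTable()
    index_of = {old: new_i for new_i, old in enumerate(kept)}
    for old in kept:
        ni = index_of[old]
        new.marks.append(table.marks[old])
        new.subordinates[ni] = list(table.subordinates.get(old, []))
    for keeper, inner in remap.table.items():
        ni = index_of[keeper]
        for removed_idx in inner:
            new.subordinates[ni].append(table.marks[removed_idx])
            new.subordinates[ni].extend(table.subordinates.get(removed_idx, []))
    return new


def prune_subordinates(table: MarkTable, params: PruneParams | None = None) -> MarkTable:
    """Greedy keep-sweep within each subordinate set; marks always survive.

    The mark participates as an already-kept node, so any subordinate it
    covers is removed; sets are pruned independently (no cross-set
    comparisons).
    """
    params = params or PruneParams()
    new = MarkTable(marks=list(table.marks))
    for idx, mark in enumerate(new.marks):
        subs = table.subordinates.get(idx, [])
        kept_nodes = [mark]
        survivors: list[Node] = []
        for j in _sweep_order(subs, list(range(len(subs)))):
            if all(keep_pair(subs[j], k, params) for k in kept_nodes):
                kept_nodes.append(subs[j])
                survivors.append(subs[j])
        new.subordinates[idx] = survivors
    return new


def prune_mark_table(table: MarkTable, params: PruneParams | None = None) -> MarkTable:
    """Full three-pass pruning: marks, remapping, subordinates."""
    params = params or PruneParams()
    _, remap = prune_marks(table.marks, params)
    remapped = remark_subordinates(remap, table)
    return prune_subordinates(remapped, params)
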