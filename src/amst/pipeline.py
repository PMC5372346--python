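"""End-to-end tracing: volume in, SWC morphology out.

Stages: binarization, mean-shift skeletonization, covered-node pruning,
adapted weight matrix (sphere-walk pathways), minimum spanning tree,
pathway fill-in, and short-spur pruning.  Every stage is deterministic, so
the same volume and configuration always produce the same SWC.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields

from .amst_graph import (
    WeightParams,
    assemble_tree,
    build_weight_matrix,
    minimum_spanning_tree,
    prune_spurs,
)
from .binarize import BinarizeParams, foreground_mask
from .meanshift import MeanShiftParams, Node, run_mean_shift
from .node_prune import PruneParams, prune_mark_table
from .sphere_path import WalkParams
from .volume_io import SWCTree, Volume

logger = logging.getLogger("amst")

__all__ = ["TraceConfig", "TraceError", "trace_volume"]


class TraceError(RuntimeError):
    """Raised when the pipeline cannot produce a reconstruction."""


@dataclass
class TraceConfig:
    """All pipeline parameters with their reference defaults.

    Defaults: intensity threshold 30, neighbor ratio 0.3, mean-shift sphere
    radius 5 with at most 100 shifts, cover threshold 3, walk sphere radius
    2 with 4 quadrants, gap penalty M = 100, pair cutoff 40, minimum spur
    length 5.  ``root`` of None picks the largest-radius node (soma-like).
    """

    intensity_threshold: float = 30.0
    ratio_threshold: float = 0.3
    ms_kernel_scale: float = 1.0
    ms_radius: float = 5.0
    ms_max_iter: int = 100
    cover_threshold: float = 3.0
    sphere_radius: float = 2.0
    gap_penalty_m: int = 100
    pair_cutoff: float = 40.0
    min_spur: float = 5.0
    root: int | None = None

    def binarize_params(self) -> BinarizeParams:
        return BinarizeParams(self.intensity_threshold, self.ratio_threshold)

    def meanshift_params(self) -> MeanShiftParams:
        return MeanShiftParams(
            kernel_scale=self.ms_kernel_scale,
            sphere_radius=self.ms_radius,
            max_iterations=self.ms_max_iter,
        )

    def prune_params(self) -> PruneParams:
        return PruneParams(self.cover_threshold)

    def walk_params(self) -> WalkParams:
        return WalkParams(sphere_radius=self.sphere_radius)

    def weight_params(self) -> WeightParams:
        return WeightParams(M=self.gap_penalty_m, pair_cutoff=self.pair_cutoff)

    def header_lines(self) -> list[str]:
        return [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]


@dataclass
class TraceResult:
    tree: SWCTree
    nodes: list[Node] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)


def trace_volume(vol: Volume, config: TraceConfig | None = None) -> TraceResult:
    """Run the full reconstruction pipeline on a volume."""
    config = config or TraceConfig()
    counts: dict[str, int] = {}

    t0 = time.perf_counter()
    mask = foreground_mask(vol, config.binarize_params())
    counts["foreground_voxels"] = mask.count()
    logger.info("binarization: %d foreground voxels (%.2fs)", counts["foreground_voxels"], time.perf_counter() - t0)
    if counts["foreground_voxels"] == 0:
        raise TraceError("no foreground voxels after binarization")

    t0 = time.perf_counter()
    table = run_mean_shift(vol, mask, config.meanshift_params())
    counts["marks"] = len(table.marks)
    counts["skeleton_nodes"] = table.total_nodes()
    logger.info("mean shift: %d marks, %d nodes (%.2fs)", counts["marks"], counts["skeleton_nodes"], time.perf_counter() - t0)

    t0 = time.perf_counter()
    pruned = prune_mark_table(table, config.prune_params())
    nodes: list[Node] = list(pruned.marks)
    for subs in pruned.subordinates.values():
        nodes.extend(subs)
    counts["pruned_nodes"] = len(nodes)
    logger.info("pruning: %d nodes kept (%.2fs)", len(nodes), time.perf_counter() - t0)
    if not nodes:
        raise TraceError("no nodes survive pruning")

    t0 = time.perf_counter()
    wmat = build_weight_matrix(nodes, vol, mask, config.weight_params(), config.walk_params())
    counts["pathways_found"] = len(wmat.pathways)
    logger.info("weight matrix: %d/%d pairs with pathways (%.2fs)", counts["pathways_found"], len(nodes) * (len(nodes) - 1) // 2, time.perf_counter() - t0)

    root = config.root
    if root is None:
        root = max(range(len(nodes)), key=lambda i: (nodes[i].radius, -i))
    parents = minimum_spanning_tree(wmat, root=root)
    tree = assemble_tree(parents, wmat, nodes, vol, mask)
    counts["tree_records"] = len(tree)
    tree = prune_spurs(tree, config.min_spur)
    counts["final_records"] = len(tree)
    logger.info("tree: %d records after spur pruning", counts["final_records"])
    return TraceResult(tree=tree, nodes=nodes, stage_counts=counts)
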