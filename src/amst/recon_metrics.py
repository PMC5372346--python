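"""Reconstruction-difference scores between two SWC morphologies.

Four bidirectional nearest-neighbor summaries, computed on trees resampled
at a fixed step so node density does not bias the scores:

* **ESA** — entire-structure average: mean nearest-sample distance,
  averaged over both directions.
* **DSA** — different-structure average: mean of the nearest-sample
  distances that exceed the visibility threshold (0 when none do).
* **PDS** — percentage of different structure: fraction of samples whose
  nearest-sample distance exceeds the threshold, averaged over both
  directions.
* **MDNN** — max distance of the trees' nodes: the largest nearest-sample
  distance in either direction.

The visibility threshold defaults to 2 voxels: spatial divergence above it
counts as noticeably different structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .volume_io import SWCTree

__all__ = ["MetricParams", "DiffScores", "resample_tree", "diff_scores"]


@dataclass
class MetricParams:
    """resample_step: segment subdivision spacing, voxels (default 1.0);
    visible_threshold: distance above which a sample counts as different
    structure, voxels (default 2.0)."""

    resample_step: float = 1.0
    visible_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.resample_step <= 0 or self.visible_threshold <= 0:
            raise ValueError("resample_step and visible_threshold must be > 0")


@dataclass
class DiffScores:
    esa: float
    dsa: float
    pds: float
    mdnn: float

    def as_dict(self) -> dict[str, float]:
        return {"esa": self.esa, "dsa": self.dsa, "pds": self.pds, "mdnn": self.mdnn}


def resample_tree(tree: SWCTree, step: float = 1.0) -> np.ndarray:
    """Sample points along every parent-child segment at <= ``step`` spacing.

    Original endpoints are retained, so the resampled polyline has the same
    total length as the tree's edges.  Returns an (n, 3) array.
    """
    by_id = {r.id: r for r in tree.records}
    samples = [r.position() for r in tree.records]
    for r in tree.records:
        if r.parent == -1:
            continue
        p = by_id[r.parent].position()
        q = r.position()
        length = float(np.linalg.norm(q - p))
        if length == 0:
            continue
        nseg = int(np.ceil(length / step))
        for k in range(1, nseg):
            samples.append(p + (q - p) * (k / nseg))
    return np.array(samples) if samples else np.empty((0, 3))


def diff_scores(
    a: SWCTree, b: SWCTree, params: MetricParams | None = None
) -> DiffScores:
    """Compute ESA, DSA, PDS and MDNN between two reconstructions.

    Symmetric in its arguments and invariant under record reordering.
    Raises on an empty tree.
    """
    params = params or MetricParams()
    pa = resample_tree(a, params.resample_step)
    pb = resample_tree(b, params.resample_step)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("diff_scores requires two nonempty trees")
    d_a, _ = cKDTree(pb).query(pa)
    d_b, _ = cKDTree(pa).query(pb)
    thr = params.visible_threshold
    esa = (float(d_a.mean()) + float(d_b.mean())) / 2.0
    pds = (float((d_a > thr).mean()) + float((d_b > thr).mean())) / 2.0
    over = np.concatenate([d_a[d_a > thr], d_b[d_b > thr]])
    dsa = float(over.mean()) if len(over) else 0.0
    mdnn = float(max(d_a.max(), d_b.max()))
    return DiffScores(esa=esa, dsa=dsa, pds=pds, mdnn=mdnn)
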