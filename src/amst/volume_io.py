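"""Image-stack and SWC morphology I/O.

Coordinate convention used across the package: coordinates are 0-based voxel
indices in an ``(x, y, z)`` frame, where ``x`` runs fastest within a stack
slice and ``z`` indexes slices.  TIFF pages are stored on disk as
``(z, y, x)`` planes and transposed on read.  SWC coordinates are emitted in
the same voxel frame; no physical-unit scaling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Volume",
    "SWCRecord",
    "SWCTree",
    "read_volume",
    "write_volume",
    "read_swc",
    "write_swc",
]


@dataclass
class Volume:
    """A 3D grayscale image stack with 8-bit intensities.

    ``data`` is indexed ``data[x, y, z]`` with values in [0, 255].
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if any(s <= 0 for s in self.data.shape):
            raise ValueError(f"Volume dims must be positive, got {self.data.shape}")
        if self.data.dtype != np.uint8:
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < 0 or hi > 255:
                raise ValueError(f"intensities outside [0, 255]: [{lo}, {hi}]")
            self.data = self.data.astype(np.uint8)

    @property
    def dims(self) -> tuple[int, int, int]:
        """(nx, ny, nz) voxel counts."""
        return self.data.shape  # type: ignore[return-value]

    def intensity_at(self, point) -> int:
        """Intensity of the voxel nearest to a (possibly fractional) point."""
        idx = np.clip(
            np.rint(np.asarray(point, dtype=float)).astype(int),
            0,
            np.array(self.dims) - 1,
        )
        return int(self.data[tuple(idx)])


@dataclass
class SWCRecord:
    """One morphology node: ``id type x y z radius parent``.

    ``type_code`` follows the SWC convention (1 soma, 2 axon, 3 dendrite,
    0 undefined); ``parent`` is -1 for a root.  Radii are in voxels and are
    at least 1.0 — the smallest resolvable foreground node.
    """

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent: int

    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class SWCTree:
    """An ordered list of SWC records forming a forest of rooted trees."""

    records: list[SWCRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        """Check id uniqueness, parent references, radii and acyclicity."""
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in SWC tree")
        id_set = set(ids)
        parent_of: dict[int, int] = {}
        for r in self.records:
            if r.id <= 0:
                raise ValueError(f"non-positive id {r.id}")
            if r.radius < 1.0 - 1e-9:
                raise ValueError(f"record {r.id}: radius {r.radius} < 1.0")
            if r.parent != -1 and r.parent not in id_set:
                raise ValueError(f"record {r.id}: dangling parent {r.parent}")
            parent_of[r.id] = r.parent
        # cycle check by walking each node to a root
        state: dict[int, int] = {}  # 0 visiting, 1 done
        for start in ids:
            chain = []
            node = start
            while node != -1 and state.get(node) != 1:
                if state.get(node) == 0:
                    raise ValueError(f"parent cycle through id {node}")
                state[node] = 0
                chain.append(node)
                node = parent_of[node]
            for n in chain:
                state[n] = 1

    def roots(self) -> list[SWCRecord]:
        return [r for r in self.records if r.parent == -1]

    def children_map(self) -> dict[int, list[int]]:
        kids: dict[int, list[int]] = {r.id: [] for r in self.records}
        for r in self.records:
            if r.parent != -1:
                kids[r.parent].append(r.id)
        return kids

    def positions(self) -> np.ndarray:
        """(n, 3) array of node coordinates in record order."""
        if not self.records:
            return np.empty((0, 3))
        return np.array([[r.x, r.y, r.z] for r in self.records], dtype=float)


def read_volume(path) -> Volume:
    """Read a single- or multi-page grayscale TIFF as a :class:`Volume`.

    16-bit images are linearly min-max rescaled to [0, 255] so the default
    intensity threshold keeps its meaning; 8-bit images are read verbatim.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    if arr.ndim != 3:
        raise ValueError(f"expected a grayscale stack, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if arr.dtype != np.uint8:
        arr = arr.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        if hi > lo:
            arr = (arr - lo) * (255.0 / (hi - lo))
        else:
            arr = np.zeros_like(arr)
        arr = np.rint(arr).astype(np.uint8)
    # (z, y, x) pages -> (x, y, z)
    return Volume(np.ascontiguousarray(arr.transpose(2, 1, 0)))


def write_volume(vol: Volume, path) -> None:
    """Write a :class:`Volume` as an 8-bit multi-page TIFF ((z, y, x) pages)."""
    tifffile.imwrite(str(path), vol.data.transpose(2, 1, 0), photometric="minisblack")


def write_swc(tree: SWCTree, path, header: list[str] | None = None) -> None:
    """Write a morphology in 7-column SWC format.

    Records are emitted in topological order (parent before child); the tree
    is validated before anything is written.  ``header`` lines are prefixed
    with ``#``.
    """
    tree.validate()
    by_id = {r.id: r for r in tree.records}
    kids = tree.children_map()
    ordered: list[SWCRecord] = []
    stack = [r.id for r in reversed(tree.roots())]
    while stack:
        nid = stack.pop()
        ordered.append(by_id[nid])
        stack.extend(reversed(kids[nid]))
    lines = []
    for h in header or []:
        lines.append(f"# {h}")
    for r in ordered:
        lines.append(
            f"{r.id} {r.type_code} {r.x:.3f} {r.y:.3f} {r.z:.3f} "
            f"{r.radius:.3f} {r.parent}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path) -> SWCTree:
    """Read a 7-column SWC file; ``#`` comments and blank lines are skipped."""
    records: list[SWCRecord] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        records.append(
            SWCRecord(
                id=int(parts[0]),
                type_code=int(parts[1]),
                x=float(parts[2]),
                y=float(parts[3]),
                z=float(parts[4]),
                radius=float(parts[5]),
                parent=int(parts[6]),
            )
        )
    tree = SWCTree(records)
    ids = {r.id for r in records}
    for r in records:
        if r.parent != -1 and r.parent not in ids:
            raise ValueError(f"{path}: record {r.id} references missing parent {r.parent}")
    return tree
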