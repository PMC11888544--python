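"""Region partitions: tissue label maps and (possibly overlapping) block covers.

A partition defines the image regions over which temporal subspaces are
estimated and applied. Two modes exist:

* label-map mode — disjoint, exhaustive tissue segments (one label per pixel);
* block mode — a grid of rectangular blocks that may overlap, in which case a
  pixel can belong to several regions and reassembly averages over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RegionPartition:
    """Partition of an H x W grid into n regions."""

    shape: tuple
    region_names: list
    label_map: np.ndarray = None
    is_blocks: bool = False
    block_index_sets: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.is_blocks:
            if not self.block_index_sets:
                raise ValueError("block mode requires block_index_sets")
            cov = self.coverage()
            if np.any(cov == 0):
                raise ValueError("every pixel must belong to at least one block")
        else:
            if self.label_map is None:
                raise ValueError("label-map mode requires label_map")
            self.label_map = np.asarray(self.label_map)
            if self.label_map.shape != tuple(self.shape):
                raise ValueError("label_map shape mismatch")
            if self.label_map.min() < 0 or self.label_map.max() >= self.n_regions:
                raise ValueError("labels must lie in [0, n_regions)")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def indices(self, i: int) -> np.ndarray:
        """Flat pixel indices of region i."""
        if self.is_blocks:
            return self.block_index_sets[i]
        return np.flatnonzero(self.label_map.ravel() == i)

    def coverage(self) -> np.ndarray:
        """Per-pixel count of covering regions (flat, length H*W)."""
        n_pix = int(np.prod(self.shape))
        cov = np.zeros(n_pix, dtype=np.int32)
        for i in range(self.n_regions):
            if self.is_blocks:
                np.add.at(cov, self.block_index_sets[i], 1)
            else:
                cov[self.indices(i)] += 1
        return cov


def partition_from_labels(label_map: np.ndarray, region_names: list) -> RegionPartition:
    label_map = np.asarray(label_map)
    return RegionPartition(
        shape=label_map.shape, region_names=list(region_names), label_map=label_map
    )


def partition_blocks(
    height: int, width: int, block_grid: int, overlap_fraction: float = 0.5
) -> RegionPartition:
    """Cover an image with a block_grid x block_grid grid of rectangular blocks.

    Each base block is extended by overlap_fraction of its size on every side
    (clipped at the image border), so interior pixels are covered by several
    blocks when overlap_fraction > 0.
    """
    if block_grid < 1:
        raise ValueError("block_grid must be >= 1")
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    if block_grid > height or block_grid > width:
        raise ValueError("block larger than image")
    row_edges = np.linspace(0, height, block_grid + 1).astype(int)
    col_edges = np.linspace(0, width, block_grid + 1).astype(int)
    index_sets = []
    names = []
    for bi in range(block_grid):
        for bj in range(block_grid):
            r0, r1 = row_edges[bi], row_edges[bi + 1]
            c0, c1 = col_edges[bj], col_edges[bj + 1]
            er = int(round(overlap_fraction * (r1 - r0)))
            ec = int(round(overlap_fraction * (c1 - c0)))
            rr0, rr1 = max(0, r0 - er), min(height, r1 + er)
            cc0, cc1 = max(0, c0 - ec), min(width, c1 + ec)
            rows = np.arange(rr0, rr1)
            cols = np.arange(cc0, cc1)
            idx = (rows[:, None] * width + cols[None, :]).ravel()
            index_sets.append(idx)
            names.append(f"block_{bi}_{bj}")
    return RegionPartition(
        shape=(height, width),
        region_names=names,
        is_blocks=True,
        block_index_sets=index_sets,
    )


def whole_image_partition(height: int, width: int) -> RegionPartition:
    """Single region covering the whole image (globally-low-rank mode)."""
    return partition_from_labels(np.zeros((height, width), dtype=np.int16), ["image"])


def scale_partition(partition: RegionPartition, factor: int) -> RegionPartition:
    """Upscale a label-map partition by an integer factor (nearest neighbour)."""
    if partition.is_blocks:
        raise ValueError("rescale block partitions by rebuilding with partition_blocks")
    lm = np.repeat(np.repeat(partition.label_map, factor, axis=0), factor, axis=1)
    return partition_from_labels(lm, partition.region_names)
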