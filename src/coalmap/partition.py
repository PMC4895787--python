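"""Local-partition inference via the Four-Gamete Test.

Under the infinite-sites model two biallelic sites that exhibit all four
gametes (00, 01, 10, 11) cannot descend from a single non-recombining
genealogy, so a change of local genealogy (recombination, or here a locus
boundary with free recombination between loci) must fall between them.
Breakpoints are placed by a greedy left-to-right scan that grows a maximal
block of mutually compatible sites and starts a new block at the first
site incompatible with *any* member of the current block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import HaploidAlignment

__all__ = ["PartitionSet", "four_gamete_compatible", "infer_breakpoints"]


@dataclass(frozen=True)
class PartitionSet:
    """Contiguous site partitions tiling an alignment.

    Stored as 0-based half-open ``(start, end)`` ranges; file I/O converts
    to the 1-based inclusive convention.  ``breakpoints`` (the partition
    start sites plus the trivial final endpoint) are derived.
    """

    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError("empty partition set")
        expect = self.ranges[0][0]
        for start, end in self.ranges:
            if start != expect or end <= start:
                raise ValueError(
                    "partitions must tile the sites without gaps or overlaps"
                )
            expect = end
        if self.ranges[0][0] != 0:
            raise ValueError("first partition must start at site 0")

    @classmethod
    def from_ranges(cls, ranges) -> "PartitionSet":
        return cls(tuple((int(s), int(e)) for s, e in ranges))

    @classmethod
    def single(cls, n_sites: int) -> "PartitionSet":
        return cls(((0, int(n_sites)),))

    @property
    def n_sites(self) -> int:
        return self.ranges[-1][1]

    @property
    def n_partitions(self) -> int:
        return len(self.ranges)

    @property
    def breakpoints(self) -> np.ndarray:
        """Block start indices plus the final endpoint (0-based)."""
        return np.array([s for s, _ in self.ranges] + [self.n_sites])

    def partition_of_site(self, j: int) -> int:
        if not 0 <= j < self.n_sites:
            raise IndexError(f"site {j} outside [0, {self.n_sites})")
        starts = np.array([s for s, _ in self.ranges])
        return int(np.searchsorted(starts, j, side="right") - 1)

    def site_indices(self, ell: int) -> np.ndarray:
        start, end = self.ranges[ell]
        return np.arange(start, end)


def _check_binary(col: np.ndarray) -> np.ndarray:
    col = np.asarray(col)
    if not np.isin(col, (0, 1)).all():
        raise ValueError("columns must be binary (entries in {0, 1})")
    return col.astype(np.int8)


def four_gamete_compatible(col_i, col_j) -> bool:
    """True unless all four gametes 00/01/10/11 occur between two sites."""
    a = _check_binary(col_i)
    b = _check_binary(col_j)
    if a.shape != b.shape:
        raise ValueError("columns must have equal length")
    gametes = {(int(x), int(y)) for x, y in zip(a, b)}
    return len(gametes) < 4


def infer_breakpoints(aln: HaploidAlignment) -> PartitionSet:
    """Greedy Four-Gamete-Test scan into maximal compatible blocks.

    Each new site is tested against every site of the current block; the
    first incompatibility closes the block.  With infinite sites and
    complete intra-locus linkage, every true locus ends up inside a single
    block, so inferred partitions are a coarsening of the true loci.
    """
    G = aln.genotypes.astype(np.int64)
    n, k = G.shape
    ranges: list[tuple[int, int]] = []
    start = 0
    for j in range(1, k):
        block = G[:, start:j]
        col = G[:, j]
        # gamete counts of site j against the whole block, vectorized:
        # all four positive for some block site => incompatible
        n11 = col @ block
        n10 = col.sum() - n11
        n01 = block.sum(axis=0) - n11
        n00 = n - n11 - n10 - n01
        if np.any((n11 > 0) & (n10 > 0) & (n01 > 0) & (n00 > 0)):
            ranges.append((start, j))
            start = j
    ranges.append((start, k))
    return PartitionSet.from_ranges(ranges)
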