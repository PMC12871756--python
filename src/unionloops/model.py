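"""Core genomic coordinate and loop data model.

Conventions used throughout the package:

* all genomic coordinates are 0-based, half-open;
* contact-matrix pixels are stored upper-triangular (``bin1 <= bin2``);
  input pixels with ``bin1 > bin2`` are flipped on ingestion;
* inter-chromosomal (trans) pixels are rejected — only cis contacts are
  analyzed;
* distances between pixels are Euclidean in base pairs on the points
  ``(bin1 * resolution, bin2 * resolution)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BinnedChrom",
    "Pixel",
    "Anchor",
    "PeakInterval",
    "to_bin",
    "bin_to_anchor",
    "pixel_distance",
]


@dataclass(frozen=True)
class BinnedChrom:
    """A chromosome binned at a fixed resolution.

    Parameters
    ----------
    name
        Chromosome identifier. Matching elsewhere is by exact name
        (no ``chr1`` vs ``1`` aliasing).
    length_bp
        Chromosome length in base pairs.
    resolution
        Bin size in base pairs.
    """

    name: str
    length_bp: int
    resolution: int

    def __post_init__(self) -> None:
        if self.length_bp < 0:
            raise ValueError(f"negative chromosome length: {self.length_bp}")
        if self.resolution <= 0:
            raise ValueError(f"non-positive resolution: {self.resolution}")

    @property
    def n_bins(self) -> int:
        return -(-self.length_bp // self.resolution)  # ceil division

    def contains_bin(self, b: int) -> bool:
        return 0 <= b < self.n_bins


@dataclass(frozen=True, order=True)
class Pixel:
    """One bin-pair of an intra-chromosomal contact matrix.

    ``bin1`` is the upstream (row) anchor, ``bin2`` the downstream (column)
    anchor; ``bin1 <= bin2`` always holds (the constructor flips if needed).
    """

    chrom: str
    bin1: int
    bin2: int

    def __post_init__(self) -> None:
        if self.bin1 < 0 or self.bin2 < 0:
            raise ValueError(f"negative bin index in {self!r}")
        if self.bin1 > self.bin2:
            # canonical upper-triangular form
            b1, b2 = self.bin2, self.bin1
            object.__setattr__(self, "bin1", b1)
            object.__setattr__(self, "bin2", b2)

    @property
    def distance_bins(self) -> int:
        return self.bin2 - self.bin1

    def anchors(self, resolution: int) -> tuple["Anchor", "Anchor"]:
        return (
            bin_to_anchor(self.chrom, self.bin1, resolution),
            bin_to_anchor(self.chrom, self.bin2, resolution),
        )


@dataclass(frozen=True)
class Anchor:
    """One resolution-sized genomic interval (a loop anchor)."""

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp < 0 or self.end_bp <= self.start_bp:
            raise ValueError(f"invalid anchor interval {self!r}")


@dataclass(frozen=True)
class PeakInterval:
    """A 0-based half-open genomic interval, e.g. a CTCF/RAD21 peak."""

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError(f"empty or inverted interval {self!r}")


def to_bin(position_bp: int, resolution: int) -> int:
    """Map a genomic position to its bin index (floor division).

    The inverse anchor of bin ``b`` is ``[b * resolution, (b+1) * resolution)``.
    """
    if resolution <= 0:
        raise ValueError(f"non-positive resolution: {resolution}")
    if position_bp < 0:
        raise ValueError(f"negative position: {position_bp}")
    return position_bp // resolution


def bin_to_anchor(chrom: str, bin_index: int, resolution: int) -> Anchor:
    """Reconstruct the genomic interval covered by a bin."""
    if bin_index < 0:
        raise ValueError(f"negative bin index: {bin_index}")
    return Anchor(chrom, bin_index * resolution, (bin_index + 1) * resolution)


def pixel_distance(p: Pixel, q: Pixel, resolution: int) -> float:
    """Euclidean distance in bp between two pixels of one chromosome.

    Pixels are treated as points ``(bin1 * resolution, bin2 * resolution)``;
    this is the metric underlying radius-based clustering of enriched pixels.
    """
    if p.chrom != q.chrom:
        raise ValueError(f"pixels on different chromosomes: {p.chrom} vs {q.chrom}")
    dx = (p.bin1 - q.bin1) * resolution
    dy = (p.bin2 - q.bin2) * resolution
    return math.hypot(dx, dy)
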