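"""Genomic interval primitives and the overlap engine.

Every coordinate inside the package is 0-based, half-open ``[start, end)``.
BED-family inputs are taken verbatim; VCF positions are decremented on read
and incremented on write (see :mod:`sesvlink.io`).  Chromosome names are
compared after stripping an optional ``chr`` prefix (configurable), so mixed
GRCh38 naming dialects interoperate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree


class ParseError(ValueError):
    """A malformed line or record in an input file."""


class ConfigError(ValueError):
    """An invalid or inconsistent configuration value."""


def chrom_key(chrom: str, normalize: bool = True) -> str:
    """Canonical chromosome name used for all comparisons.

    With ``normalize`` (the default) an optional leading ``chr`` prefix is
    stripped, so ``chr17`` and ``17`` match.
    """
    if normalize and chrom.lower().startswith("chr"):
        return chrom[3:]
    return chrom


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def same_chrom(self, other: "GenomicInterval", normalize: bool = True) -> bool:
        return chrom_key(self.chrom, normalize) == chrom_key(other.chrom, normalize)

    def intersection_length(self, other: "GenomicInterval", normalize: bool = True) -> int:
        """Length of the overlap in bp; 0 when disjoint or on other chroms."""
        if not self.same_chrom(other, normalize):
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def distance_to_point(self, pos: int) -> int:
        """Gap in bp between the interval and the 1-bp span at ``pos``.

        0 when the position lies inside or abuts the interval, consistent
        with :func:`interval_gap` on half-open spans.
        """
        return max(self.start - (pos + 1), pos - self.end, 0)


@dataclass(frozen=True)
class Sample:
    """A cohort member with optional recurrence-free-survival annotation.

    ``rfs_time`` is in months; ``rfs_event`` is True for an observed
    recurrence and False for censoring.  Both are present or both absent.
    """

    sample_id: str
    cohort: str
    rfs_time: Optional[float] = None
    rfs_event: Optional[bool] = None

    def __post_init__(self) -> None:
        if (self.rfs_time is None) != (self.rfs_event is None):
            raise ValueError(
                f"sample {self.sample_id}: rfs_time and rfs_event must be "
                "given together"
            )
        if self.rfs_time is not None and self.rfs_time < 0:
            raise ValueError(f"sample {self.sample_id}: negative rfs_time")


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with its transcription start site.

    The TSS is derived from the strand: ``location.start`` on the plus (or
    unspecified) strand, ``location.end - 1`` on the minus strand.
    """

    gene_id: str
    symbol: str
    location: GenomicInterval

    @property
    def tss(self) -> int:
        if self.location.strand == "-":
            return self.location.end - 1
        return self.location.start

    @property
    def chrom(self) -> str:
        return self.location.chrom


def find_overlaps(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    normalize: bool = True,
) -> list[tuple[int, int, int]]:
    """All intersecting pairs between two interval lists.

    Returns ``(index_a, index_b, overlap_length)`` triples for every pair on
    the same chromosome with an intersection of at least 1 bp (partial or
    complete overlap), sorted by ``(index_a, index_b)``.  Input order is
    arbitrary; an interval tree over ``set_b`` is queried per element of
    ``set_a``.
    """
    trees: dict[str, IntervalTree] = {}
    for j, b in enumerate(set_b):
        trees.setdefault(chrom_key(b.chrom, normalize), IntervalTree()).addi(
            b.start, b.end, j
        )
    out: list[tuple[int, int, int]] = []
    for i, a in enumerate(set_a):
        tree = trees.get(chrom_key(a.chrom, normalize))
        if tree is None:
            continue
        for hit in tree.overlap(a.start, a.end):
            j = hit.data
            b = set_b[j]
            out.append((i, j, min(a.end, b.end) - max(a.start, b.start)))
    out.sort()
    return out


def interval_gap(
    a: GenomicInterval, b: GenomicInterval, normalize: bool = True
) -> Optional[int]:
    """Distance in bp between the nearest edges of two intervals.

    0 when the intervals overlap or abut; ``None`` (undefined) when they lie
    on different chromosomes.
    """
    if not a.same_chrom(b, normalize):
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def sort_intervals(
    intervals: Iterable[GenomicInterval], normalize: bool = True
) -> list[GenomicInterval]:
    """Deterministic ordering: (normalized chrom, start, end)."""
    return sorted(
        intervals, key=lambda iv: (chrom_key(iv.chrom, normalize), iv.start, iv.end)
    )
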