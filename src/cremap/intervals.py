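"""Genomic interval primitives and overlap algebra.

All coordinates are 0-based, half-open (BED convention): an interval
``(chrom, start, end)`` covers the bases ``start .. end-1``. Readers for
1-based dialects (e.g. GTF) convert at the boundary, so every function in
this package can assume this single convention.

Strand is carried on intervals but never consulted by overlap tests; it
matters only for the sign of TSS distances (see :mod:`cremap.annotation`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored half-open coordinate span.

    Parameters
    ----------
    chrom : str
        Chromosome label; any non-empty string.
    start : int
        0-based inclusive start, ``>= 0``.
    end : int
        Exclusive end, ``> start`` (empty intervals are rejected).
    strand : str
        One of ``+``, ``-`` or ``.`` (unspecified). Ignored by overlap
        logic; used only for distance signs downstream.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: start={self.start}, end={self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """The central base of the interval, left-biased for even lengths.

        Equals ``floor((start + end - 1) / 2)`` — the left median of the
        covered bases — so it is always a base inside the interval.
        """
        return (self.start + self.end - 1) // 2


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` and ``b`` share at least one base.

    Same chromosome and ``a.start < b.end and b.start < a.end``; half-open
    abutment (``a.end == b.start``) does not overlap. Strand is ignored.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def midpoint(a: GenomicInterval) -> int:
    """Central base of ``a``; see :attr:`GenomicInterval.midpoint`."""
    return a.midpoint


def span_union(intervals: Iterable[GenomicInterval]) -> GenomicInterval:
    """Smallest interval covering all inputs (must share one chromosome)."""
    ivs = list(intervals)
    if not ivs:
        raise ValueError("span_union of empty collection")
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) > 1:
        raise ValueError(f"span_union across chromosomes: {sorted(chroms)}")
    return GenomicInterval(
        ivs[0].chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs)
    )


class IntervalIndex:
    """Chromosome-partitioned interval tree over a fixed subject list.

    Supports repeated overlap queries against the same subjects; the
    subjects keep their original list indices.
    """

    def __init__(self, subjects: Sequence[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        self.subjects = list(subjects)
        for idx, iv in enumerate(self.subjects):
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, idx
            )

    def query(self, q: GenomicInterval) -> list[int]:
        """Indices of all subjects overlapping ``q``, ascending."""
        tree = self._trees.get(q.chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.overlap(q.start, q.end))


def bulk_overlap(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> dict[int, list[int]]:
    """Map each query index to the ascending indices of overlapping subjects.

    Every query index appears in the result, with an empty list when
    nothing overlaps.
    """
    index = IntervalIndex(subject)
    return {qi: index.query(q) for qi, q in enumerate(query)}
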