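"""Disjoint genomic interval sets with 0-based half-open coordinates.

All interval arithmetic in the pipeline (exon unions, intron derivation,
shared-region subtraction, read-block overlap) goes through this module so
that coordinate conventions live in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of arbitrary intervals as a sorted disjoint list.

    Empty intervals (start >= end) are dropped. Touching intervals
    ([0,5),[5,9)) are merged into one.
    """
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def subtract_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """a minus b; both must be sorted and disjoint."""
    out: list[Interval] = []
    bi = 0
    nb = len(b)
    for s, e in a:
        cur = s
        while bi < nb and b[bi][1] <= cur:
            bi += 1
        j = bi
        while j < nb and b[j][0] < e:
            bs, be = b[j]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            j += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two sorted disjoint interval lists."""
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def overlap_length(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    return sum(e - s for s, e in intersect_intervals(a, b))


def multicov_regions(intervals: Iterable[Interval], min_depth: int = 2) -> list[Interval]:
    """Bases covered by at least `min_depth` of the given intervals.

    Sweep over start/end events; used to find genomic space claimed by
    two or more gene spans.
    """
    events: list[tuple[int, int]] = []
    for s, e in intervals:
        if e > s:
            events.append((s, 1))
            events.append((e, -1))
    events.sort()
    out: list[Interval] = []
    depth = 0
    start = None
    for pos, delta in events:
        new_depth = depth + delta
        if depth < min_depth <= new_depth:
            start = pos
        elif new_depth < min_depth <= depth:
            assert start is not None
            if pos > start:
                out.append((start, pos))
            start = None
        depth = new_depth
    return merge_intervals(out)


@dataclass(frozen=True)
class IntervalSet:
    """Disjoint sorted 0-based half-open intervals on one chromosome strand.

    strand '.' means strandless (e.g. the shared-region audit trail).
    """

    chrom: str
    strand: str = "."
    intervals: tuple[Interval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        merged = tuple(merge_intervals(self.intervals))
        object.__setattr__(self, "intervals", merged)

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def __bool__(self) -> bool:
        return bool(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    def subtract(self, other: Sequence[Interval] | "IntervalSet") -> "IntervalSet":
        other_ivs = list(other.intervals) if isinstance(other, IntervalSet) else merge_intervals(other)
        return IntervalSet(self.chrom, self.strand, tuple(subtract_intervals(list(self.intervals), other_ivs)))

    def intersect(self, other: Sequence[Interval] | "IntervalSet") -> "IntervalSet":
        other_ivs = list(other.intervals) if isinstance(other, IntervalSet) else merge_intervals(other)
        return IntervalSet(self.chrom, self.strand, tuple(intersect_intervals(list(self.intervals), other_ivs)))

    def union(self, other: Sequence[Interval] | "IntervalSet") -> "IntervalSet":
        other_ivs = list(other.intervals) if isinstance(other, IntervalSet) else list(other)
        return IntervalSet(self.chrom, self.strand, tuple(list(self.intervals) + other_ivs))

    def overlap_length(self, blocks: Sequence[Interval]) -> int:
        return overlap_length(list(self.intervals), merge_intervals(blocks))

    def contains_point(self, pos: int) -> bool:
        for s, e in self.intervals:
            if s <= pos < e:
                return True
            if s > pos:
                break
        return False
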