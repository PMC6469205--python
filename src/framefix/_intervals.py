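"""Half-open integer interval arithmetic shared by binning, QC and masking code.

All intervals are ``(start, end)`` with ``0 <= start < end``; positions are
integers and ``end`` is exclusive. This is the single coordinate convention
used throughout the package.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def _validated(intervals: Iterable[Sequence[int]]) -> list[Interval]:
    out = []
    for iv in intervals:
        a, b = int(iv[0]), int(iv[1])
        if a >= b:
            raise ValueError(f"invalid half-open interval ({a}, {b}): start must be < end")
        out.append((a, b))
    return out


def merge(intervals: Iterable[Sequence[int]]) -> list[Interval]:
    """Merge overlapping or abutting intervals into a sorted disjoint list."""
    ivs = sorted(_validated(intervals))
    merged: list[Interval] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            if b > merged[-1][1]:
                merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


def union_length(intervals: Iterable[Sequence[int]]) -> int:
    """Number of integer positions covered by the union of the intervals."""
    return sum(b - a for a, b in merge(intervals))


def overlap_length(a: Interval, b: Interval) -> int:
    """Length of the intersection of two half-open intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def complement(intervals: Iterable[Sequence[int]], start: int, end: int) -> list[Interval]:
    """Maximal sub-intervals of [start, end) not covered by ``intervals``."""
    if start >= end:
        raise ValueError("empty domain")
    gaps: list[Interval] = []
    cursor = start
    for a, b in merge(intervals):
        a, b = max(a, start), min(b, end)
        if a >= b:
            continue
        if a > cursor:
            gaps.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < end:
        gaps.append((cursor, end))
    return gaps
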