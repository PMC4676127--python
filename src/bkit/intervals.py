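"""Interval arithmetic on 0-based half-open (start, end) spans.

Every genomic mask, gap, duplication block and gene span in this package is
carried as a plain list/array of ``(start, end)`` pairs per scaffold.  The
helpers here are deliberately small: merge, intersect, subtract, total length
and point membership, all on sorted integer arrays.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or touching intervals into a sorted disjoint set."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    if not ivs:
        return []
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = out[-1]
        if s <= le:
            out[-1] = (ls, max(le, e))
        else:
            out.append((s, e))
    return out


def intersect_intervals(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Intersection of two interval sets (each may be unsorted/overlapping)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract_intervals(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Set difference a \\ b."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def coverage_mask(intervals: Iterable[Interval], length: int) -> np.ndarray:
    """Boolean array of ``length`` positions, True inside any interval."""
    mask = np.zeros(int(length), dtype=bool)
    for s, e in intervals:
        mask[max(0, int(s)):min(int(length), int(e))] = True
    return mask


def points_in_intervals(positions: Sequence[int], intervals: Iterable[Interval]) -> np.ndarray:
    """For 0-based positions, True where the position lies inside an interval."""
    pos = np.asarray(positions, dtype=np.int64)
    ivs = merge_intervals(intervals)
    if not ivs:
        return np.zeros(pos.shape, dtype=bool)
    starts = np.array([s for s, _ in ivs], dtype=np.int64)
    ends = np.array([e for _, e in ivs], dtype=np.int64)
    idx = np.searchsorted(starts, pos, side="right") - 1
    inside = idx >= 0
    inside[inside] &= pos[inside] < ends[idx[inside]]
    return inside
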