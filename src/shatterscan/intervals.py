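"""Closed-interval arithmetic on 1-based genomic coordinates.

Every interval is a ``(start, end)`` pair with ``start <= end`` and the
interval contains both endpoints, so its length is ``end - start + 1``.
Two intervals are merged when they overlap or abut (``[1, 5]`` and
``[6, 10]`` union to ``[1, 10]``).
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """True when closed intervals [a_start, a_end] and [b_start, b_end] intersect."""
    return a_start <= b_end and b_start <= a_end


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping or abutting closed intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if s <= e)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s + 1 for s, e in merge(intervals))


def subtract(base: Interval, cuts: Iterable[Interval]) -> list[Interval]:
    """Remove *cuts* from the closed interval *base*."""
    s0, e0 = int(base[0]), int(base[1])
    out: list[Interval] = []
    cursor = s0
    for cs, ce in merge(cuts):
        if ce < cursor or cs > e0:
            continue
        if cs > cursor:
            out.append((cursor, cs - 1))
        cursor = max(cursor, ce + 1)
        if cursor > e0:
            break
    if cursor <= e0:
        out.append((cursor, e0))
    return out


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Intersection of two closed-interval sets (both merged first)."""
    xs, ys = merge(a), merge(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(xs) and j < len(ys):
        s = max(xs[i][0], ys[j][0])
        e = min(xs[i][1], ys[j][1])
        if s <= e:
            out.append((s, e))
        if xs[i][1] < ys[j][1]:
            i += 1
        else:
            j += 1
    return out
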