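"""Small interval utilities over 0-based half-open intervals."""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


def merge_intervals(intervals: Iterable[Interval], min_gap: int = 0) -> List[Interval]:
    """Merge overlapping/adjacent intervals; intervals closer than ``min_gap`` merge too."""
    ivs = sorted(intervals)
    if not ivs:
        return []
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s - out[-1][1] < min_gap or s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def union_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def complement(intervals: Iterable[Interval], length: int) -> List[Interval]:
    """Intervals of [0, length) not covered by the input."""
    out = []
    pos = 0
    for s, e in merge_intervals(intervals):
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        out.append((pos, length))
    return out
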