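"""Half-open interval arithmetic on a single chromosome.

Intervals are (start, end) pairs in a common coordinate system (cM for the
synthetic dialect, where 1 cM = 1 Mb). All functions expect and return lists
sorted by start with end > start.
"""

from __future__ import annotations


def merge(intervals: list[tuple[float, float]], gap: float = 0.0) -> list[tuple[float, float]]:
    """Union of intervals, bridging gaps of at most ``gap``."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s - out[-1][1] <= gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def intersect(a: list[tuple[float, float]], b: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Pairwise intersection of two sorted, disjoint interval lists."""
    out: list[tuple[float, float]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total(intervals: list[tuple[float, float]]) -> float:
    return sum(e - s for s, e in intervals)
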