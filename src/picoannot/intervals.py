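"""Half-open genomic interval arithmetic shared across modules.

All coordinates in memory are 0-based half-open ``(start, end)`` tuples;
GFF3 on disk is 1-based closed and BED is 0-based half-open, converted at
the I/O boundary.
"""
from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def intersect_len(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def contains(outer: Interval, inner: Interval) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def span(ivs: Sequence[Interval]) -> Interval:
    return (min(s for s, _ in ivs), max(e for _, e in ivs))


def merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted list of disjoint intervals."""
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_length(ivs: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge_intervals(ivs))


class UnionFind:
    """Disjoint-set forest with path compression, used for locus grouping
    and transfrag linking."""

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri

    def groups(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for i in range(len(self.parent)):
            out.setdefault(self.find(i), []).append(i)
        return out
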