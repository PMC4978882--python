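"""Sorted, disjoint, half-open genomic interval sets.

Both hotspot truth and hotspot calls are represented as an
:class:`IntervalSet`: a sorted list of pairwise-disjoint ``[start, end)``
bp intervals, each optionally carrying a payload (a truth fold, or
per-call diagnostics).  All coordinates are 0-based half-open
throughout the package, matching BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator

__all__ = ["IntervalSet"]


@dataclass
class IntervalSet:
    """Sorted pairwise-disjoint half-open intervals with optional payloads.

    ``data[i]`` is the payload attached to ``intervals[i]`` (``None`` when
    absent).  Construction sorts the input and rejects overlaps; use
    :meth:`merged` to union overlapping/abutting raw intervals first.
    """

    intervals: list[tuple[int, int]] = field(default_factory=list)
    data: list[Any] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.data:
            self.data = [None] * len(self.intervals)
        if len(self.data) != len(self.intervals):
            raise ValueError("data must parallel intervals")
        order = sorted(range(len(self.intervals)), key=lambda i: self.intervals[i])
        self.intervals = [tuple(map(int, self.intervals[i])) for i in order]
        self.data = [self.data[i] for i in order]
        prev_end = None
        for start, end in self.intervals:
            if end <= start:
                raise ValueError(f"empty or inverted interval [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError("intervals overlap")
            prev_end = end

    @classmethod
    def merged(cls, raw: Iterable[tuple[int, int]]) -> "IntervalSet":
        """Union of raw intervals, merging overlapping *or abutting* ones."""
        raw = sorted((int(s), int(e)) for s, e in raw if e > s)
        out: list[tuple[int, int]] = []
        for s, e in raw:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return cls(out)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    @property
    def total_bp(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def overlap_bp(self, other: "IntervalSet") -> int:
        """Total bp in the intersection with another interval set."""
        total = 0
        i = j = 0
        a, b = self.intervals, other.intervals
        while i < len(a) and j < len(b):
            lo = max(a[i][0], b[j][0])
            hi = min(a[i][1], b[j][1])
            if hi > lo:
                total += hi - lo
            if a[i][1] <= b[j][1]:
                i += 1
            else:
                j += 1
        return total

    def subset(self, keep) -> "IntervalSet":
        """Intervals whose (interval, payload) satisfy ``keep``."""
        pairs = [(iv, d) for iv, d in zip(self.intervals, self.data) if keep(iv, d)]
        return IntervalSet([p[0] for p in pairs], [p[1] for p in pairs])
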