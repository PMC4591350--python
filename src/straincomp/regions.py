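"""Interval algebra on genomes: merged region sets, complements, lengths.

Coordinates are 0-based half-open throughout the library; exporters that
produce reports for human reading convert to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

Interval = Tuple[int, int]

__all__ = ["RegionSet", "merge_intervals", "complement_intervals"]


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge intervals; touching intervals ([0,5) + [5,8)) coalesce."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: List[Interval] = []
    for s, e in ivs:
        if e < s:
            raise ValueError(f"interval end {e} before start {s}")
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return [iv for iv in out if iv[1] > iv[0]]


def complement_intervals(intervals: List[Interval], length: int) -> List[Interval]:
    """Complement of a *merged* interval list within [0, length)."""
    out: List[Interval] = []
    prev = 0
    for s, e in intervals:
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return out


@dataclass
class RegionSet:
    """Sorted, disjoint, maximally merged intervals per replicon of one genome."""

    genome_id: str
    regions: Dict[str, List[Interval]] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls, genome_id: str, per_replicon: Dict[str, Iterable[Interval]]
    ) -> "RegionSet":
        return cls(
            genome_id,
            {rep: merge_intervals(ivs) for rep, ivs in per_replicon.items()},
        )

    def add(self, replicon: str, start: int, end: int) -> None:
        self.regions[replicon] = merge_intervals(
            self.regions.get(replicon, []) + [(start, end)]
        )

    def total_length(self) -> int:
        return sum(e - s for ivs in self.regions.values() for s, e in ivs)

    def n_regions(self) -> int:
        return sum(len(ivs) for ivs in self.regions.values())

    def complement(self, replicon_lengths: Dict[str, int]) -> "RegionSet":
        """Uncovered intervals within each declared replicon."""
        comp = {
            rep: complement_intervals(self.regions.get(rep, []), length)
            for rep, length in replicon_lengths.items()
        }
        return RegionSet(self.genome_id, {r: ivs for r, ivs in comp.items()})

    def filter_min_length(self, min_len: int, strict: bool = True) -> "RegionSet":
        """Keep regions longer than ``min_len`` (strict) or >= (not strict)."""
        keep = (lambda s, e: e - s > min_len) if strict else (lambda s, e: e - s >= min_len)
        return RegionSet(
            self.genome_id,
            {
                rep: [iv for iv in ivs if keep(*iv)]
                for rep, ivs in self.regions.items()
            },
        )

    def intersect_length(self, other: "RegionSet") -> int:
        """Total overlap in bp with another RegionSet (same genome coordinates)."""
        total = 0
        for rep, ivs in self.regions.items():
            others = other.regions.get(rep, [])
            i = j = 0
            while i < len(ivs) and j < len(others):
                s = max(ivs[i][0], others[j][0])
                e = min(ivs[i][1], others[j][1])
                if e > s:
                    total += e - s
                if ivs[i][1] < others[j][1]:
                    i += 1
                else:
                    j += 1
        return total

    def jaccard(self, other: "RegionSet") -> float:
        """Base-level Jaccard similarity with another RegionSet."""
        inter = self.intersect_length(other)
        union = self.total_length() + other.total_length() - inter
        return inter / union if union else 1.0

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for rep in sorted(self.regions):
                for s, e in self.regions[rep]:
                    fh.write(f"{rep}\t{s}\t{e}\n")
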