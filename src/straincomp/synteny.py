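"""Order conservation of matched regions between two genomes.

Filtered alignment segments are ranked along each genome (by declared
replicon order, then start coordinate).  Two criteria are offered:

* ``strict_rank`` (default): a segment is order-conserved when its rank
  on genome A equals its rank on genome B — a rank-identity criterion
  that yields small conserved fractions for heavily rearranged genomes;
* ``lis``: the length of the longest subsequence whose B-ranks increase
  with A-ranks (classic longest-increasing-subsequence relaxation).

The criterion behind published "same order" counts is rarely stated
operationally; both interpretations are kept and the choice is explicit.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import List, Sequence

from .align_io import AlignmentSegment

__all__ = ["OrderConservation", "order_conservation", "longest_increasing_subsequence"]


@dataclass
class OrderConservation:
    genome_a: str
    genome_b: str
    n_same_order: int
    n_total: int
    pct: float
    mode: str
    undefined: bool = False  # True when n_total == 0

    def cell(self) -> str:
        return f"{self.n_same_order}/{self.n_total} ({self.pct:.2f}%)"


def longest_increasing_subsequence(seq: Sequence[int]) -> int:
    """Length of the longest strictly increasing subsequence."""
    tails: List[int] = []
    for x in seq:
        i = bisect_left(tails, x)
        if i == len(tails):
            tails.append(x)
        else:
            tails[i] = x
    return len(tails)


def order_conservation(
    segments: List[AlignmentSegment],
    replicon_order_a: Sequence[str],
    replicon_order_b: Sequence[str],
    mode: str = "strict_rank",
) -> OrderConservation:
    """Count matched regions occupying the same rank in both genomes."""
    if mode not in ("strict_rank", "lis"):
        raise ValueError(f"unknown mode {mode!r}")
    if not segments:
        ga = gb = ""
        return OrderConservation(ga, gb, 0, 0, 0.0, mode, undefined=True)

    ga = segments[0].query_genome
    gb = segments[0].target_genome
    idx_a = {rep: i for i, rep in enumerate(replicon_order_a)}
    idx_b = {rep: i for i, rep in enumerate(replicon_order_b)}

    def key_a(s: AlignmentSegment):
        return (idx_a[s.query_replicon], s.q_start, s.q_end)

    def key_b(s: AlignmentSegment):
        return (idx_b[s.target_replicon], s.t_start, s.t_end)

    order_a = sorted(range(len(segments)), key=lambda i: key_a(segments[i]))
    rank_b = {
        i: r for r, i in enumerate(sorted(range(len(segments)), key=lambda i: key_b(segments[i])))
    }
    perm = [rank_b[i] for i in order_a]  # B-rank of the segment at each A-rank

    if mode == "strict_rank":
        n_same = sum(1 for a_rank, b_rank in enumerate(perm) if a_rank == b_rank)
    else:
        n_same = longest_increasing_subsequence(perm)

    n_total = len(segments)
    pct = round(100.0 * n_same / n_total, 2)
    return OrderConservation(ga, gb, n_same, n_total, pct, mode)
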