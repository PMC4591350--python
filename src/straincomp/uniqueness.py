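"""Coverage, similarity and uniqueness from filtered alignment segments.

Given all-vs-all pairwise local alignments (filtered to drop segments
shorter than 300 bp), this module computes, per genome:

* the union of aligned bases against each other genome (coverage);
* the similarity matrix: percent of a genome's bases shared with each
  other genome, pooled over all replicons (chromosome + plasmids) -- this
  matrix is asymmetric because the two genomes differ in size;
* unique regions: the complement of the coverage union over *all* other
  genomes, keeping complement intervals strictly longer than a minimum
  (300 bp by default);
* a uniqueness report: unique length, percent of genome, number of
  regions, ORFs falling in unique regions, the share of those ORFs
  annotated as hypothetical proteins, and the share of unique bases not
  covered by any CDS.

A base aligned by many segments counts once (union semantics), so
repeated sequence cannot inflate similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

from .align_io import AlignmentSegment
from .annotation import CdsRecord
from .genome import Genome
from .regions import RegionSet, merge_intervals

__all__ = [
    "coverage_union",
    "similarity_matrix",
    "unique_regions",
    "uniqueness_report",
    "UniquenessReport",
]


def coverage_union(segments: Iterable[AlignmentSegment], reference: Genome) -> RegionSet:
    """Union of query intervals of ``segments`` on the reference genome."""
    per_rep: Dict[str, List[Tuple[int, int]]] = {}
    lengths = reference.replicon_lengths
    for seg in segments:
        if seg.query_genome != reference.genome_id:
            raise ValueError(
                f"segment query genome {seg.query_genome!r} is not {reference.genome_id!r}"
            )
        if seg.query_replicon not in lengths:
            raise KeyError(
                f"unknown replicon {seg.query_replicon!r} on genome {reference.genome_id!r}"
            )
        if seg.q_end > lengths[seg.query_replicon]:
            raise ValueError(
                f"segment end {seg.q_end} beyond replicon "
                f"{seg.query_replicon!r} length {lengths[seg.query_replicon]}"
            )
        per_rep.setdefault(seg.query_replicon, []).append((seg.q_start, seg.q_end))
    return RegionSet(
        reference.genome_id, {rep: merge_intervals(ivs) for rep, ivs in per_rep.items()}
    )


def similarity_matrix(
    pair_segments: Dict[Tuple[str, str], List[AlignmentSegment]],
    genomes: List[Genome],
) -> pd.DataFrame:
    """Percent of genome i bases covered by alignments to genome j.

    ``pair_segments[(i, j)]`` holds segments whose query side is genome
    ``i`` and target side genome ``j``.  The diagonal is NaN (not
    applicable).  Entries are rounded to 2 decimals.
    """
    by_id = {g.genome_id: g for g in genomes}
    ids = [g.genome_id for g in genomes]
    mat = pd.DataFrame(np.nan, index=ids, columns=ids)
    for gi in ids:
        total = by_id[gi].total_length
        if total == 0:
            raise ZeroDivisionError(f"genome {gi!r} has zero length")
        for gj in ids:
            if gi == gj:
                continue
            segs = pair_segments.get((gi, gj), [])
            covered = coverage_union(segs, by_id[gi]).total_length()
            mat.loc[gi, gj] = round(100.0 * covered / total, 2)
    return mat


def unique_regions(
    reference: Genome,
    segments: Iterable[AlignmentSegment],
    min_unique_len: int = 300,
) -> RegionSet:
    """Complement of the coverage union over all other genomes.

    ``segments`` must contain every filtered segment whose query side is
    the reference genome, against every other genome in the comparison
    set.  Complement intervals are kept only when strictly longer than
    ``min_unique_len``.
    """
    covered = coverage_union(segments, reference)
    comp = covered.complement(reference.replicon_lengths)
    return comp.filter_min_length(min_unique_len, strict=True)


@dataclass
class UniquenessReport:
    genome_id: str
    unique_length_bp: int
    unique_pct: float
    n_unique_regions: int
    orfs_in_unique: int
    pct_hypothetical_orfs: float
    pct_not_annotated: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "Length of unique regions (bp)": self.unique_length_bp,
                "Unique regions (%)": self.unique_pct,
                "ORFs in unique regions": self.orfs_in_unique,
                "ORFs of hypothetical proteins in unique regions (%)": self.pct_hypothetical_orfs,
                "Not Annotated (%)": self.pct_not_annotated,
            },
            name=self.genome_id,
        )


def _overlap_with(regions: List[Tuple[int, int]], start: int, end: int) -> int:
    total = 0
    for s, e in regions:
        if s >= end:
            break
        lo, hi = max(s, start), min(e, end)
        if hi > lo:
            total += hi - lo
    return total


def uniqueness_report(
    unique: RegionSet,
    cds: List[CdsRecord],
    genome: Genome,
    membership_fraction: float = 0.5,
) -> UniquenessReport:
    """Summarise a genome's unique regions against its CDS annotation.

    A CDS is counted as "in" a unique region when at least
    ``membership_fraction`` of its length overlaps the unique set.
    """
    if genome.total_length == 0:
        raise ZeroDivisionError(f"genome {genome.genome_id!r} has zero length")
    unique_len = unique.total_length()
    unique_pct = 100.0 * unique_len / genome.total_length

    orfs_in = 0
    hypothetical_in = 0
    cds_regions: Dict[str, List[Tuple[int, int]]] = {}
    for rec in cds:
        cds_regions.setdefault(rec.replicon, []).append((rec.start, rec.end))
        regions = unique.regions.get(rec.replicon, [])
        if rec.length == 0:
            continue
        ov = _overlap_with(regions, rec.start, rec.end)
        if ov >= membership_fraction * rec.length:
            orfs_in += 1
            if rec.is_hypothetical:
                hypothetical_in += 1

    cds_set = RegionSet.from_intervals(genome.genome_id, cds_regions)
    annotated_in_unique = unique.intersect_length(cds_set)
    not_annotated = unique_len - annotated_in_unique

    return UniquenessReport(
        genome_id=genome.genome_id,
        unique_length_bp=unique_len,
        unique_pct=round(unique_pct, 2),
        n_unique_regions=unique.n_regions(),
        orfs_in_unique=orfs_in,
        pct_hypothetical_orfs=round(100.0 * hypothetical_in / orfs_in, 2) if orfs_in else 0.0,
        pct_not_annotated=round(100.0 * not_annotated / unique_len, 2) if unique_len else 0.0,
    )
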