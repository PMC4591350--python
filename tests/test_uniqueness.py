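"""Interval algebra, similarity and uniqueness against per-base oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import bool_cover, regions_from_bool
from straincomp.align_io import AlignmentSegment, anchor_align, filter_segments, transpose_segments
from straincomp.annotation import CdsRecord
from straincomp.genome import Genome
from straincomp.regions import RegionSet, complement_intervals, merge_intervals
from straincomp.uniqueness import (
    coverage_union,
    similarity_matrix,
    unique_regions,
    uniqueness_report,
)

interval_lists = st.lists(
    st.tuples(st.integers(0, 995), st.integers(1, 120)).map(
        lambda t: (t[0], min(t[0] + t[1], 1000))
    ),
    max_size=30,
)


def make_segments(intervals, qg="gA", tg="gB", rep="r1"):
    return [
        AlignmentSegment(qg, rep, s, e, tg, rep, s, e, "+") for s, e in intervals
    ]


class TestIntervalOracle:
    @settings(max_examples=200, derandomize=True)
    @given(interval_lists)
    def test_merge_matches_boolean_oracle(self, intervals):
        merged = merge_intervals(intervals)
        assert merged == regions_from_bool(bool_cover(intervals, 1000))

    @settings(max_examples=200, derandomize=True)
    @given(interval_lists)
    def test_complement_matches_boolean_oracle(self, intervals):
        merged = merge_intervals(intervals)
        comp = complement_intervals(merged, 1000)
        assert comp == regions_from_bool(~bool_cover(intervals, 1000))

    @settings(max_examples=200, derandomize=True)
    @given(interval_lists)
    def test_coverage_plus_complement_conserve_length(self, intervals):
        merged = merge_intervals(intervals)
        comp = complement_intervals(merged, 1000)
        covered = sum(e - s for s, e in merged)
        free = sum(e - s for s, e in comp)
        assert covered + free == 1000


class TestCoverageUnion:
    def test_overlapping_segments_merge(self):
        g = Genome("gA", {"r1": "A" * 10000})
        cov = coverage_union(make_segments([(0, 4000), (3500, 6000)]), g)
        assert cov.regions == {"r1": [(0, 6000)]}
        assert cov.total_length() == 6000

    def test_no_segments_empty(self):
        g = Genome("gA", {"r1": "A" * 1000})
        assert coverage_union([], g).total_length() == 0

    def test_unknown_replicon_raises(self):
        g = Genome("gA", {"r1": "A" * 1000})
        with pytest.raises(KeyError, match="unknown replicon"):
            coverage_union(make_segments([(0, 10)], rep="rX"), g)


class TestSimilarityMatrix:
    def test_self_identity_alignment_is_100(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 10000))
        a = Genome("gA", {"r1": seq})
        b = Genome("gB", {"r1": seq})
        segs = filter_segments(anchor_align(a, b))
        pairs = {("gA", "gB"): segs, ("gB", "gA"): transpose_segments(segs)}
        mat = similarity_matrix(pairs, [a, b])
        assert mat.loc["gA", "gB"] == 100.00
        assert np.isnan(mat.loc["gA", "gA"])

    def test_partial_coverage_percent(self):
        g1 = Genome("gA", {"r1": "A" * 10000})
        g2 = Genome("gB", {"r1": "A" * 10000})
        pairs = {("gA", "gB"): make_segments([(0, 4000), (3500, 6000)])}
        mat = similarity_matrix(pairs, [g1, g2])
        assert mat.loc["gA", "gB"] == 60.00
        assert mat.loc["gB", "gA"] == 0.0

    def test_zero_length_genome_raises(self):
        with pytest.raises(ZeroDivisionError):
            similarity_matrix({}, [Genome("gA", {"r1": ""})])


class TestUniqueRegions:
    def test_short_gaps_rejected(self):
        g = Genome("gA", {"r1": "A" * 10000})
        segs = make_segments([(0, 4000), (4200, 9900)])
        uniq = unique_regions(g, segs, min_unique_len=300)
        # gaps of 200, 100 bp: both <= 300, rejected
        assert uniq.total_length() == 0

    def test_gap_of_exactly_300_rejected_301_kept(self):
        g = Genome("gA", {"r1": "A" * 10000})
        strict = unique_regions(g, make_segments([(0, 4000), (4300, 10000)]))
        assert strict.total_length() == 0  # 300 bp gap: "longer than 300" fails
        kept = unique_regions(g, make_segments([(0, 4000), (4301, 10000)]))
        assert kept.regions["r1"] == [(4000, 4301)]

    def test_no_alignments_whole_replicon_unique(self):
        g = Genome("gA", {"r1": "A" * 5000, "r2": "A" * 200})
        uniq = unique_regions(g, [])
        assert uniq.regions["r1"] == [(0, 5000)]
        assert uniq.regions.get("r2", []) == []  # 200 bp replicon not > 300

    def test_monotone_in_comparison_set(self, tiled_six_genomes):
        genomes, _ = tiled_six_genomes
        ref = genomes[0]
        segs_by_other = {
            g.genome_id: filter_segments(anchor_align(ref, g)) for g in genomes[1:4]
        }
        pool = []
        prev = None
        for gid in segs_by_other:
            pool.extend(segs_by_other[gid])
            length = unique_regions(ref, pool).total_length()
            if prev is not None:
                assert length <= prev
            prev = length


class TestUniquenessReport:
    def test_single_hypothetical_cds_in_unique_region(self):
        g = Genome("gA", {"r1": "A" * 10000})
        uniq = RegionSet.from_intervals("gA", {"r1": [(1000, 2000)]})
        cds = [CdsRecord("c1", "r1", 1000, 2000, "+", "hypothetical protein")]
        rep = uniqueness_report(uniq, cds, g)
        assert rep.orfs_in_unique == 1
        assert rep.pct_hypothetical_orfs == 100.0
        assert rep.pct_not_annotated == 0.0
        assert rep.unique_pct == 10.0

    def test_empty_unique_set_all_zero(self):
        g = Genome("gA", {"r1": "A" * 1000})
        rep = uniqueness_report(RegionSet("gA", {}), [], g)
        assert rep.unique_length_bp == 0
        assert rep.orfs_in_unique == 0
        assert rep.pct_hypothetical_orfs == 0.0
        assert rep.pct_not_annotated == 0.0

    def test_membership_needs_half_overlap(self):
        g = Genome("gA", {"r1": "A" * 10000})
        uniq = RegionSet.from_intervals("gA", {"r1": [(0, 1000)]})
        inside = CdsRecord("in", "r1", 400, 1200, "+", "permease")  # 75% inside
        outside = CdsRecord("out", "r1", 800, 2000, "+", "permease")  # 17% inside
        rep = uniqueness_report(uniq, [inside, outside], g)
        assert rep.orfs_in_unique == 1

    def test_report_matches_truth_enumeration(self):
        """Planted unique region + planted CDSs: report equals direct counting."""
        g = Genome("gA", {"r1": "A" * 50000})
        uniq = RegionSet.from_intervals("gA", {"r1": [(10000, 14000), (20000, 21000)]})
        cds = [
            CdsRecord("c1", "r1", 10100, 11000, "+", "hypothetical protein"),
            CdsRecord("c2", "r1", 11200, 12200, "-", "oxygenase"),
            CdsRecord("c3", "r1", 19500, 20400, "+", "permease"),  # 44% in: out
            CdsRecord("c4", "r1", 30000, 30900, "+", "kinase"),  # outside
        ]
        rep = uniqueness_report(uniq, cds, g)
        assert rep.unique_length_bp == 5000
        assert rep.orfs_in_unique == 2
        assert rep.pct_hypothetical_orfs == 50.0
        # annotated bases inside unique: c1 900 + c2 1000 + c3 overlap 400
        assert rep.pct_not_annotated == pytest.approx(100 * (5000 - 2300) / 5000)
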