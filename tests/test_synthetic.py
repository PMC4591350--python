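"""Synthetic-data generator: planted truth, determinism, closed forms."""

import numpy as np
import pytest
from scipy.stats import binom

from straincomp.models import MODELS, gompertz
from straincomp.synthetic import (
    simulate_cds_annotation,
    simulate_genome_set,
    simulate_pm_curve,
    simulate_pm_plate,
)


class TestGenomeSet:
    def test_one_shared_one_unique_per_genome(self):
        genomes, truths = simulate_genome_set(
            2, [[20000], [20000]], [(5000, [0, 1])], [(2000, 0), (2000, 1)], seed=1
        )
        for gid in ("g1", "g2"):
            assert len(truths[gid].planted_shared_blocks) == 1
            assert truths[gid].planted_unique_regions.n_regions() == 1

    def test_shared_blocks_are_verbatim_copies(self):
        genomes, truths = simulate_genome_set(
            3, [[30000]] * 3, [(5000, [0, 1, 2]), (3000, [0, 2])], [(2000, 1)], seed=5
        )
        by_id = {g.genome_id: g for g in genomes}
        for gid, truth in truths.items():
            for rep, s, e, partners in truth.planted_shared_blocks:
                block = by_id[gid].replicons[rep][s:e]
                for partner in partners:
                    partner_seq = "".join(by_id[partner].replicons.values())
                    assert block in partner_seq

    def test_seeded_determinism_byte_identical(self, tmp_path):
        paths = []
        for run in (1, 2):
            g, _ = simulate_genome_set(2, [[10000], [10000]], [(2000, [0, 1])], seed=7)
            p = tmp_path / f"run{run}.fasta"
            g[0].to_fasta(p)
            g[1].to_fasta(tmp_path / f"run{run}b.fasta")
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_rearrange_changes_block_order(self):
        spec = [(1000, [0, 1, 2]) for _ in range(20)]
        _, truths = simulate_genome_set(3, [[30000]] * 3, spec, rearrange=True, seed=3)
        # rank the shared blocks by coordinate within each genome and check
        # that at least one genome pair disagrees on the ordering
        orders = {}
        for gid, truth in truths.items():
            blocks = sorted(truth.planted_shared_blocks, key=lambda b: (b[0], b[1]))
            orders[gid] = [b[1] for b in blocks]
        # block identity is recoverable via the sequence; compare rank patterns
        # through coordinates of the same start offsets across genomes
        assert len({tuple(o) for o in orders.values()}) >= 1  # sanity
        seqs = {}
        genomes, _ = simulate_genome_set(3, [[30000]] * 3, spec, rearrange=True, seed=3)
        by_id = {g.genome_id: g for g in genomes}
        for gid, truth in truths.items():
            ranked = []
            for rep, s, e, _ in sorted(truth.planted_shared_blocks, key=lambda b: b[1]):
                ranked.append(by_id[gid].replicons[rep][s:e])
            seqs[gid] = ranked
        same_order_pairs = sum(
            seqs[a] == seqs[b] for a, b in [("g1", "g2"), ("g1", "g3"), ("g2", "g3")]
        )
        assert same_order_pairs < 3  # order differs for at least one pair

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="capacity"):
            simulate_genome_set(1, [[5000]], [(3000, [0]), (3000, [0])], seed=0)

    def test_shared_and_unique_disjoint_within_genome(self):
        _, truths = simulate_genome_set(
            2, [[20000], [20000]], [(4000, [0, 1])], [(3000, 0)], seed=9
        )
        t = truths["g1"]
        shared = [(r, s, e) for r, s, e, _ in t.planted_shared_blocks]
        for rep, ivs in t.planted_unique_regions.regions.items():
            for us, ue in ivs:
                for r, s, e in shared:
                    if r == rep:
                        assert ue <= s or us >= e


class TestCdsAnnotation:
    def test_zero_hypothetical_fraction(self):
        g, _ = simulate_genome_set(1, [[50000]], seed=2)
        cds = simulate_cds_annotation(g[0], hypothetical_fraction=0.0, seed=2)
        assert cds and all(not c.is_hypothetical for c in cds)

    def test_hypothetical_fraction_within_binomial_interval(self):
        g, _ = simulate_genome_set(1, [[2_000_000]], seed=3)
        cds = simulate_cds_annotation(
            g[0], density=0.5, hypothetical_fraction=0.4, seed=3
        )
        n = len(cds)
        assert n == 1000
        k = sum(c.is_hypothetical for c in cds)
        lo, hi = binom.ppf([0.005, 0.995], n, 0.4)
        assert lo <= k <= hi

    def test_cds_non_overlapping_and_in_bounds(self):
        g, _ = simulate_genome_set(1, [[40000]], seed=4)
        cds = simulate_cds_annotation(g[0], seed=4)
        by_rep = {}
        for c in cds:
            assert 0 <= c.start < c.end <= len(g[0].replicons[c.replicon])
            by_rep.setdefault(c.replicon, []).append((c.start, c.end))
        for ivs in by_rep.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_degenerate_category_weights(self):
        g, _ = simulate_genome_set(1, [[30000]], seed=5)
        cds = simulate_cds_annotation(
            g[0], category_weights={"OnlyCat": 1.0}, seed=5
        )
        assert cds and all(c.category == "OnlyCat" for c in cds)

    def test_overdense_plan_raises(self):
        g, _ = simulate_genome_set(1, [[10000]], seed=6)
        with pytest.raises(ValueError, match="place"):
            simulate_cds_annotation(g[0], density=5.0, mean_cds_len=900, seed=6)


class TestPmCurve:
    def test_gompertz_value_at_lag(self):
        c = simulate_pm_curve("gompertz", (100, 10, 5, 0))
        i = np.argmin(np.abs(c.times - 5.0))
        assert c.signals[i] == pytest.approx(100 * np.exp(-np.e), abs=1e-9)

    @pytest.mark.parametrize("model", ["logistic", "gompertz", "richards"])
    def test_zero_amplitude_constant(self, model):
        c = simulate_pm_curve(model, (0, 10, 5, 7))
        assert np.allclose(c.signals, 7.0)

    @pytest.mark.parametrize("model", ["logistic", "gompertz", "richards"])
    def test_limit_is_baseline_plus_amplitude(self, model):
        t = np.array([0.0, 1e5, 1e6])
        c = simulate_pm_curve(model, (150, 10, 5, 20), t_grid=t)
        assert c.signals[-1] == pytest.approx(170.0, rel=1e-9)

    @pytest.mark.parametrize("model", ["logistic", "gompertz", "richards"])
    def test_noiseless_equals_closed_form(self, model):
        params = dict(A=120.0, mu=15.0, lambda_=4.0, y0=8.0)
        if model == "richards":
            params["nu"] = 2.0
        c = simulate_pm_curve(model, params)
        assert np.allclose(c.signals, MODELS[model](c.times, **params), atol=1e-9)

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            simulate_pm_curve("gompertz", (-1, 10, 5, 0))
        with pytest.raises(ValueError):
            simulate_pm_curve("gompertz", (100, 10, 5, 0), noise_sd=-1)


class TestPmPlate:
    def test_symmetric_plate_all_none(self):
        effect = {
            f"s{i}": {"a": (100, 10, 5, 0), "b": (100, 10, 5, 0)} for i in range(5)
        }
        _, truth = simulate_pm_plate(("a", "b"), effect, seed=1)
        assert all(v == "none" for v in truth.specific_for.values())

    def test_planted_specific_substrate(self):
        effect = {
            "hit": {"a": (200, 10, 5, 0), "b": (0, 10, 5, 0)},
            "flat": {"a": (100, 10, 5, 0), "b": (100, 10, 5, 0)},
        }
        _, truth = simulate_pm_plate(("a", "b"), effect, seed=2)
        assert truth.specific_for == {"hit": "a", "flat": "none"}

    def test_seeded_determinism(self):
        effect = {
            f"s{i:02d}": {"a": (150, 12, 4, 5), "b": (80, 12, 4, 5)} for i in range(96)
        }
        c1, _ = simulate_pm_plate(("a", "b"), effect, noise_sd=5, seed=11)
        c2, _ = simulate_pm_plate(("a", "b"), effect, noise_sd=5, seed=11)
        assert len(c1) == 96 * 2 * 2
        for x, y in zip(c1, c2):
            assert np.array_equal(x.signals, y.signals)

    def test_missing_strain_params_raise(self):
        with pytest.raises(ValueError, match="no parameters"):
            simulate_pm_plate(("a", "b"), {"s": {"a": (1, 1, 1, 0)}}, seed=0)
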