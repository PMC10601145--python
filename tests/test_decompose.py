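"""Wraparound decomposition: oracle equivalence, event classification,
summary arithmetic and positional enrichment."""

import math

import numpy as np
import pytest

from _oracles import (
    apply_unit_ops,
    min_distance_to_tandem_array,
    random_tandem_mutant,
)
from chromend.decompose import (
    ADDITION,
    DELETION,
    SUBSTITUTION,
    classify_variants,
    decompose,
    positional_enrichment,
    summarize,
)

UNIT = "TTTAGGG"


class TestDecompose:
    def test_exact_tandem_array_has_zero_cost(self):
        d = decompose(UNIT * 3)
        assert d.total_cost == 0
        assert len(d.units) == 3
        assert [u.start for u in d.units] == [0, 7, 14]
        assert d.events == []

    def test_deletion_and_addition_classified(self):
        # one unit lost a T, another gained a G
        d = decompose("TTAGGG" + UNIT + "TTTAGGGG")
        assert d.total_cost == 2
        evs = classify_variants(d)
        assert [(e.kind, e.unit_index) for e in evs] == [
            (DELETION, 0),
            (ADDITION, 2),
        ]
        assert evs[0].ref_base == "T"
        assert evs[1].obs_base == "G"
        assert evs[0].tract_offset < evs[1].tract_offset

    def test_single_substitution(self):
        d = decompose("TTTACGG")
        assert d.total_cost == 1
        (e,) = d.events
        assert (e.kind, e.ref_base, e.obs_base, e.unit_position) == (
            SUBSTITUTION, "G", "C", 4,
        )

    def test_two_base_insertion_becomes_consecutive_additions(self):
        d = decompose("TTTAGGGGG")
        assert d.total_cost == 2
        evs = classify_variants(d)
        assert [e.kind for e in evs] == [ADDITION, ADDITION]
        assert evs[1].tract_offset == evs[0].tract_offset + 1
        assert {e.obs_base for e in evs} == {"G"}

    def test_empty_tract_rejected(self):
        with pytest.raises(ValueError):
            decompose("")

    def test_indels_placed_leftmost_in_homopolymer_runs(self):
        # deletion of one T in TTT is reported at the first T
        d = decompose("TTAGGG")
        (e,) = d.events
        assert (e.kind, e.tract_offset, e.unit_position) == (DELETION, 0, 0)
        # insertion of a G in GGG reported before the first G
        d = decompose("TTTAGGGG")
        (e,) = d.events
        assert (e.kind, e.tract_offset, e.unit_position) == (ADDITION, 4, 4)

    def test_oracle_equivalence_on_random_mutants(self, rng):
        for _ in range(60):
            tract = random_tandem_mutant(rng, UNIT)
            d = decompose(tract)
            assert d.total_cost == min_distance_to_tandem_array(tract, UNIT), tract

    def test_units_tile_the_tract_and_reconstruct_it(self, rng):
        for _ in range(40):
            tract = random_tandem_mutant(rng, UNIT)
            d = decompose(tract)
            pos = 0
            rebuilt = []
            for u in d.units:
                assert u.start == pos
                pos = u.end
                rebuilt.append(apply_unit_ops(UNIT, u))
            assert pos == len(tract)
            assert "".join(rebuilt) == tract
            assert d.total_cost == len(d.events)

    def test_single_insertion_raises_cost_by_at_most_one(self, rng):
        for _ in range(20):
            tract = random_tandem_mutant(rng, UNIT)
            base_cost = decompose(tract).total_cost
            pos = int(rng.integers(len(tract) + 1))
            ins = "ACGT"[int(rng.integers(4))]
            mutated = tract[:pos] + ins + tract[pos:]
            assert decompose(mutated).total_cost <= base_cost + 1

    def test_free_start_excuses_a_mid_unit_interior_edge(self):
        tract = "AGGG" + UNIT * 3  # starts mid-unit
        anchored = decompose(tract)
        assert anchored.total_cost == 3  # charges the missing TTT
        free = decompose(tract, free_start=True)
        assert free.total_cost == 0
        assert free.units[0].partial
        assert classify_variants(free) == []


class TestSummarize:
    def test_percent_arithmetic(self):
        events = [
            decompose("TTTAGGGG").events[0]
            for _ in range(7)
        ]
        s = summarize(events, tract_length=700)
        assert s.percent[ADDITION] == 1.0
        assert s.percent_all == 1.0
        assert s.counts[ADDITION] == 7

    def test_no_events(self):
        s = summarize([], tract_length=500)
        assert s.percent_all == 0.0
        assert all(v == 0 for v in s.percent.values())
        assert s.base_breakdown[DELETION] == {}

    def test_percent_all_is_exact_sum(self, rng):
        cfgd = dict(p_sub=0.01, p_ins=0.02, p_del=0.03)
        from chromend.simulate import SimulationConfig, simulate_chromosome_end

        seq, truth = simulate_chromosome_end(
            SimulationConfig(seed=3, unit_count=500, subtel_length=0, **cfgd)
        )
        d = decompose(seq.residues)
        s = summarize(classify_variants(d), len(seq.residues))
        assert s.percent_all == (
            s.percent[SUBSTITUTION] + s.percent[ADDITION] + s.percent[DELETION]
        )

    def test_base_breakdown_fractions_sum_to_one(self):
        events = (
            decompose("TTAGGG").events  # T deletion
            + decompose("TTTGGG").events  # A deletion
            + decompose("TTTAGGGG").events  # G addition
        )
        s = summarize(events, tract_length=100)
        assert sum(s.base_breakdown[DELETION].values()) == pytest.approx(1.0)
        assert s.base_breakdown[DELETION]["T"] == pytest.approx(0.5)
        assert s.base_breakdown[ADDITION] == {"G": 1.0}

    def test_histogram_covers_tract(self):
        events = decompose("TTTAGGGG" + UNIT * 100).events
        s = summarize(events, tract_length=708, bin=100)
        assert len(s.positional_histogram) == 8
        assert s.positional_histogram.sum() == len(events)

    def test_units_denominator_option(self):
        events = decompose("TTTAGGGG").events
        s = summarize(events, tract_length=700, denominator="units")
        assert s.percent[ADDITION] == pytest.approx(100 * 1 / 100)

    def test_recovery_within_binomial_error(self):
        """A 2% per-unit deletion rate is recovered as ~2/7 % per bp."""
        from chromend.simulate import SimulationConfig, simulate_chromosome_end

        U = 10_000
        p = 0.02
        seq, truth = simulate_chromosome_end(
            SimulationConfig(seed=42, unit_count=U, subtel_length=0,
                             p_sub=0.0, p_ins=0.0, p_del=p,
                             edge_multiplier=1.0)
        )
        tract = seq.residues
        s = summarize(classify_variants(decompose(tract)), len(tract))
        expected = 100 * U * p / len(tract)
        se = 100 * math.sqrt(U * p * (1 - p)) / len(tract)
        assert abs(s.percent[DELETION] - expected) <= 3 * se


class TestPositionalEnrichment:
    def _summary(self, offsets, L):
        events = [
            decompose("TTTAGGGG").events[0].__class__(
                kind=ADDITION, tract_offset=o, ref_base=None, obs_base="G",
                unit_index=0, unit_position=4,
            )
            for o in offsets
        ]
        return summarize(events, tract_length=L)

    def test_uniform_events_give_ratio_near_one(self, rng):
        L = 70_000
        offsets = rng.integers(0, L, size=2000)
        ratio = positional_enrichment(self._summary(offsets, L))
        assert 0.85 < ratio < 1.15

    def test_all_edge_events_give_infinite_marker(self):
        ratio = positional_enrichment(self._summary([0, 1, 999], 1000))
        assert math.isinf(ratio)

    def test_threefold_edge_enrichment_recovered(self):
        from chromend.simulate import SimulationConfig, simulate_chromosome_end
        from chromend.decompose import classify_variants, decompose

        seq, truth = simulate_chromosome_end(
            SimulationConfig(seed=9, unit_count=10_000, subtel_length=0,
                             p_sub=0.002, p_ins=0.01, p_del=0.02,
                             edge_fraction=0.1, edge_multiplier=3.0)
        )
        s = summarize(classify_variants(decompose(seq.residues)),
                      len(seq.residues))
        ratio = positional_enrichment(s, edge_fraction=0.1)
        assert 2.4 < ratio < 3.6
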