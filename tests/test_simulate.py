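"""Simulator ground truth: determinism, event statistics, recovery."""

import math

import pytest

from chromend.decompose import ADDITION, DELETION, SUBSTITUTION, classify_variants, decompose
from chromend.cpg import find_islands
from chromend.g4 import find_g4
from chromend.motifs import builtin_motifs, scan_fixed
from chromend.simulate import (
    SimulationConfig,
    recovery_report,
    simulate_chromosome_end,
)
from chromend.telomere import detect_telomere


class TestGeneration:
    def test_zero_rates_give_pure_array(self):
        cfg = SimulationConfig(seed=1, unit_count=50, p_sub=0, p_ins=0,
                               p_del=0, subtel_length=2000)
        seq, truth = simulate_chromosome_end(cfg)
        assert seq.residues.endswith("TTTAGGG" * 50)
        assert truth.events == []
        assert truth.tract_length == 350
        assert truth.telomere_boundary == 2000

    def test_same_seed_is_byte_identical(self):
        cfg = SimulationConfig(seed=77, unit_count=300, subtel_length=20_000,
                               island_blocks=((2_000, 400, "cpg_rich"),),
                               g4_inserts=((5_000, "GGGGTTGGGGTTGGGGTTGGGG"),))
        a, _ = simulate_chromosome_end(cfg)
        b, _ = simulate_chromosome_end(cfg)
        assert a.residues == b.residues

    def test_different_seeds_differ(self):
        a, _ = simulate_chromosome_end(SimulationConfig(seed=1, subtel_length=5000))
        b, _ = simulate_chromosome_end(SimulationConfig(seed=2, subtel_length=5000))
        assert a.residues != b.residues

    def test_deletion_count_and_t_bias_within_binomial_error(self):
        U, p, bias = 10_000, 0.02, 0.8
        cfg = SimulationConfig(seed=13, unit_count=U, p_sub=0, p_ins=0,
                               p_del=p, del_T_bias=bias, subtel_length=0,
                               edge_multiplier=1.0)
        _, truth = simulate_chromosome_end(cfg)
        dels = [e for e in truth.events if e.kind == DELETION]
        se_n = math.sqrt(U * p * (1 - p))
        assert abs(len(dels) - U * p) <= 3 * se_n
        t_frac = sum(1 for e in dels if e.ref_base == "T") / len(dels)
        se_f = math.sqrt(bias * (1 - bias) / len(dels))
        assert abs(t_frac - bias) <= 3 * se_f

    def test_events_reapply_to_the_emitted_sequence(self):
        """Ground-truth events are consistent with the emitted tract."""
        cfg = SimulationConfig(seed=5, unit_count=400, subtel_length=0)
        seq, truth = simulate_chromosome_end(cfg)
        # rebuild the tract from the pure array by applying the events
        unit = cfg.consensus
        rebuilt = []
        offset = 0
        events = iter(sorted(truth.events, key=lambda e: e.unit_index))
        ev = next(events, None)
        for i in range(cfg.unit_count):
            u = unit
            if ev is not None and ev.unit_index == i:
                p = ev.unit_position
                if ev.kind == SUBSTITUTION:
                    u = u[:p] + ev.obs_base + u[p + 1 :]
                elif ev.kind == DELETION:
                    u = u[:p] + u[p + 1 :]
                else:
                    u = u[:p] + ev.obs_base + u[p:]
                ev = next(events, None)
            rebuilt.append(u)
        assert "".join(rebuilt) == seq.residues

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="<= 1 per unit"):
            SimulationConfig(p_sub=0.5, p_ins=0.4, p_del=0.3).validate()
        with pytest.raises(ValueError, match="edge-adjusted"):
            SimulationConfig(p_del=0.3, edge_multiplier=5.0).validate()
        with pytest.raises(ValueError, match="overlap"):
            SimulationConfig(
                subtel_length=10_000,
                island_blocks=((1000, 400, "cpg_rich"),),
                g4_inserts=((1100, "GGGGTTGGGGTTGGGGTTGGGG"),),
            ).validate()
        with pytest.raises(ValueError, match="boundary guard"):
            SimulationConfig(
                subtel_length=1000,
                g4_inserts=((970, "GGGGTTGGGGTTGGGGTTGGGG"),),
            ).validate()


class TestRecovery:
    def test_zero_rate_recovery_is_perfect(self):
        cfg = SimulationConfig(seed=2, unit_count=60, p_sub=0, p_ins=0,
                               p_del=0, subtel_length=3000)
        seq, truth = simulate_chromosome_end(cfg)
        t = detect_telomere(seq, "right")
        tract = seq.residues[t.region.start :]
        events = classify_variants(decompose(tract))
        rep = recovery_report(truth, tract_start=t.region.start, events=events)
        assert rep["boundary_error_bp"] == 0
        assert rep["event_recall"] == 1.0
        assert rep["event_precision"] == 1.0

    def test_default_rate_event_recall(self):
        cfg = SimulationConfig(seed=3, unit_count=10_000, subtel_length=0,
                               edge_multiplier=1.0)
        seq, truth = simulate_chromosome_end(cfg)
        events = classify_variants(decompose(seq.residues))
        rep = recovery_report(truth, tract_start=0, events=events)
        assert rep["event_recall"] >= 0.95
        assert rep["event_precision"] >= 0.95

    def test_planted_features_recalled(self):
        g4_pattern = "GGGGTTGGGGTTGGGGTTGGGG"
        cfg = SimulationConfig(
            seed=8,
            unit_count=100,
            subtel_length=20_000,
            island_blocks=((3_000, 400, "cpg_rich"),),
            g4_inserts=((8_000, g4_pattern),),
            motif_placements=(("TTAGTCCCGGTT", 12_000, "+"),
                              ("YY1", 15_000, "-")),
        )
        seq, truth = simulate_chromosome_end(cfg)
        subtel = seq.residues[: truth.telomere_boundary]

        g4_hits = [
            (h.region.start, h.region.end)
            for h in find_g4(subtel).hits
        ]
        islands = [
            (i.region.start, i.region.end) for i in find_islands(subtel)
        ]
        by_id = {m.id: m for m in builtin_motifs()}
        motif_hits = [
            (h.region.start, h.region.end)
            for mid in ("TTAGTCCCGGTT", "YY1")
            for h in scan_fixed(subtel, by_id[mid])
        ]
        rep = recovery_report(
            truth,
            g4_intervals=g4_hits,
            island_intervals=islands,
            motif_intervals=motif_hits,
        )
        assert rep["g4_recall"] == 1.0
        assert rep["island_recall"] == 1.0
        assert rep["motif_recall"] == 1.0
        # the planted quadruplex comes back as exactly one merged hit there
        overlapping = [h for h in g4_hits if h[0] < 8_022 and h[1] > 8_000]
        assert len(overlapping) == 1

    def test_minus_strand_motif_plant_found_on_minus(self):
        cfg = SimulationConfig(seed=4, unit_count=50, subtel_length=5_000,
                               motif_placements=(("YY1", 2_000, "-"),))
        seq, truth = simulate_chromosome_end(cfg)
        by_id = {m.id: m for m in builtin_motifs()}
        hits = scan_fixed(seq.residues[:5_000], by_id["YY1"])
        assert any(
            h.region.start == 2_000 and h.strand == "-" for h in hits
        )
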