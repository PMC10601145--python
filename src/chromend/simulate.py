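"""Synthetic chromosome-end generator with exact ground truth.

The simulator emits a subtelomeric sequence (random background at a
configurable GC fraction, with optional planted satellite blocks, CpG-island
segments, G-quadruplex inserts and fixed motifs at known coordinates)
followed by a mutated terminal telomere array on the right end. The telomere
mutation process draws at most one event per 7-bp unit — a single-base
substitution, insertion or deletion — with configurable per-unit rates,
elevated rates within an edge fraction at both tract ends, a T bias for
deletions (most deletions remove one T of the TTT, turning TTTAGGG into
TTAGGG) and a G bias for insertions (most additions extend the GGG run,
producing TTTAGGGG).

Ground-truth indel events are recorded left-normalized within homopolymer
runs: which T of a TTT was deleted is unidentifiable from the sequence, so
the canonical description (the leftmost) is stored, matching the
decomposer's deterministic reporting convention.

Two guarantees keep the truth usable as an oracle: planted features may not
overlap one another or the terminal 60 bp of the subtelomere, and the
terminal 50 bp of background are redrawn until they contain no
canonical-or-1-edit telomere unit (otherwise the telomere/subtelomere
boundary itself would be ill-defined). Everything is deterministic given the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .decompose import ADDITION, DELETION, SUBSTITUTION, VariantEvent
from .motifs import builtin_motifs
from .seqio import GenomicSequence, reverse_complement
from .telomere import _coverage

BOUNDARY_GUARD = 60  # plant-free zone before the telomere, bp
SCRUB_SPAN = 50  # background redrawn here until unit-free, bp


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated chromosome end.

    Rates are per unit; at most one event is drawn per unit, with the rate
    multiplied by ``edge_multiplier`` inside the ``edge_fraction`` of units
    at each tract end. Plant coordinates are offsets into the subtelomere.
    """

    seed: int = 0
    unit_count: int = 1000
    consensus: str = "TTTAGGG"
    p_sub: float = 0.001
    p_ins: float = 0.01
    p_del: float = 0.02
    del_T_bias: float = 0.8
    ins_G_bias: float = 0.8
    edge_fraction: float = 0.1
    edge_multiplier: float = 3.0
    subtel_length: int = 100_000
    gc_background: float = 0.44
    satellite_blocks: tuple = ()  # (unit_seq, copies, offset)
    island_blocks: tuple = ()  # (offset, length, style in {cpg_rich, gc_skewed})
    g4_inserts: tuple = ()  # (offset, pattern)
    motif_placements: tuple = ()  # (motif_id_or_pattern, offset, strand)

    def validate(self) -> None:
        for p in (self.p_sub, self.p_ins, self.p_del):
            if not 0.0 <= p <= 1.0:
                raise ValueError("event probabilities must lie in [0, 1]")
        total = self.p_sub + self.p_ins + self.p_del
        if total > 1.0:
            raise ValueError("p_sub + p_ins + p_del must be <= 1 per unit")
        if total * self.edge_multiplier > 1.0:
            raise ValueError(
                "edge-adjusted event probability exceeds 1; lower the rates "
                "or edge_multiplier"
            )
        if self.edge_multiplier < 1.0:
            raise ValueError("edge_multiplier must be >= 1")
        if not 0.0 <= self.edge_fraction <= 0.5:
            raise ValueError("edge_fraction must lie in [0, 0.5]")
        if self.unit_count < 1:
            raise ValueError("unit_count must be >= 1")
        if self.subtel_length < 0:
            raise ValueError("subtel_length must be >= 0")
        # planted features: inside the subtelomere, outside the boundary
        # guard, and mutually non-overlapping
        spans = [(s, e, what) for s, e, what in self._plant_spans()]
        limit = self.subtel_length - BOUNDARY_GUARD
        for s, e, what in spans:
            if s < 0 or e > self.subtel_length:
                raise ValueError(f"plant {what} [{s}, {e}) outside subtelomere")
            if e > limit:
                raise ValueError(
                    f"plant {what} [{s}, {e}) intrudes into the {BOUNDARY_GUARD}-bp "
                    "boundary guard before the telomere"
                )
        spans.sort()
        for (s1, e1, w1), (s2, e2, w2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"plants {w1} and {w2} overlap")

    def _plant_spans(self):
        for unit, copies, off in self.satellite_blocks:
            yield off, off + len(unit) * copies, f"satellite@{off}"
        for off, length, style in self.island_blocks:
            yield off, off + length, f"island({style})@{off}"
        for off, pattern in self.g4_inserts:
            yield off, off + len(pattern), f"g4@{off}"
        for mid, off, strand in self.motif_placements:
            pat = _motif_pattern(mid)
            yield off, off + len(pat), f"motif({mid})@{off}"


@dataclass
class GroundTruth:
    """Everything the simulator knows: boundary, events, planted features."""

    telomere_boundary: int  # global coordinate of the first tract base
    tract_length: int
    events: list[VariantEvent]  # offsets relative to the tract start
    features: dict[str, list[tuple[int, int]]]  # track -> [(start, end)]
    config: SimulationConfig


def _motif_pattern(motif_id: str) -> str:
    for m in builtin_motifs():
        if m.id == motif_id and m.pattern is not None:
            return m.pattern
    if set(motif_id) <= set("ACGTN"):
        return motif_id  # raw pattern
    raise ValueError(f"unknown motif id {motif_id!r}")


def _island_block(length: int, style: str) -> str:
    if style == "cpg_rich":
        return ("CG" * ((length + 1) // 2))[:length]
    if style == "gc_skewed":
        half = length // 2
        return "G" * half + "C" * (length - half)
    raise ValueError(f"unknown island style {style!r}")


def _mutate_unit(
    unit: str, kind: str, rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[str, str, int, str | None, str | None]:
    """Apply one event to a consensus unit.

    Returns ``(mutated_unit, kind, normalized_position, ref, obs)`` with the
    position left-normalized within homopolymer runs of the consensus.
    """
    m = len(unit)
    if kind == SUBSTITUTION:
        p = int(rng.integers(m))
        ref = unit[p]
        obs = "ACGT".replace(ref, "")[int(rng.integers(3))]
        return unit[:p] + obs + unit[p + 1 :], kind, p, ref, obs
    if kind == DELETION:
        if rng.random() < cfg.del_T_bias:
            # remove one T of TTT; leftmost canonical description
            candidates = [i for i, b in enumerate(unit) if b == "T"]
        else:
            # remainder split over A and G by consensus composition (1:3)
            others = [i for i, b in enumerate(unit) if b != "T"]
            pick = others[int(rng.integers(len(others)))]
            candidates = [i for i in others if unit[i] == unit[pick]]
        p = candidates[int(rng.integers(len(candidates)))]
        while p > 0 and unit[p - 1] == unit[p]:
            p -= 1
        return unit[:p] + unit[p + 1 :], kind, p, unit[p], None
    # insertion
    if rng.random() < cfg.ins_G_bias:
        # extend the G-run: TTTAGGG -> TTTAGGGG
        obs = "G"
        p = unit.index("G")
    else:
        # non-G so the configured bias is exactly the G-addition fraction
        obs = "ACT"[int(rng.integers(3))]
        p = int(rng.integers(m + 1))
        while p > 0 and unit[p - 1] == obs:
            p -= 1
    return unit[:p] + obs + unit[p:], ADDITION, p, None, obs


def _simulate_telomere(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[str, list[VariantEvent]]:
    U = cfg.unit_count
    unit = cfg.consensus
    n_edge = int(round(cfg.edge_fraction * U))
    parts: list[str] = []
    events: list[VariantEvent] = []
    offset = 0
    for i in range(U):
        edge = i < n_edge or i >= U - n_edge
        mult = cfg.edge_multiplier if edge else 1.0
        r = rng.random()
        kind = None
        if r < cfg.p_sub * mult:
            kind = SUBSTITUTION
        elif r < (cfg.p_sub + cfg.p_ins) * mult:
            kind = ADDITION
        elif r < (cfg.p_sub + cfg.p_ins + cfg.p_del) * mult:
            kind = DELETION
        if kind is None:
            parts.append(unit)
            offset += len(unit)
            continue
        mutated, kind, p, ref, obs = _mutate_unit(unit, kind, rng, cfg)
        unit_pos = p if not (kind == ADDITION and p == len(unit)) else len(unit)
        events.append(
            VariantEvent(
                kind=kind,
                tract_offset=offset + p,
                ref_base=ref,
                obs_base=obs,
                unit_index=i,
                unit_position=unit_pos,
            )
        )
        parts.append(mutated)
        offset += len(mutated)
    return "".join(parts), events


def _background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(alphabet, size=length, p=probs)


def _scrub_boundary(
    subtel: bytearray, cfg: SimulationConfig, rng: np.random.Generator
) -> None:
    """Redraw terminal background until no 1-edit telomere unit touches the
    boundary (including junction k-mers spanning into the telomere)."""
    L = len(subtel)
    if L == 0:
        return
    span = min(SCRUB_SPAN, L)
    units = (cfg.consensus, reverse_complement(cfg.consensus))
    context = (cfg.consensus * 2)[:8]  # the telomere side of the junction
    lead = min(8, L - span)  # upstream context kept fixed
    for _ in range(200):
        window = subtel[L - span - lead :].decode() + context
        # offending = any recognized-unit base inside the scrub region itself
        # (matches fully inside the fixed contexts are harmless: they cannot
        # chain across the >21 bp clean gap to the boundary)
        if not any(
            any(_coverage(window, u)[lead : lead + span]) for u in units
        ):
            return
        fresh = _background(span, cfg.gc_background, rng)
        subtel[L - span :] = fresh.tobytes()
    raise RuntimeError("could not scrub the telomere boundary; lower gc_background")


def simulate_chromosome_end(
    config: SimulationConfig,
) -> tuple[GenomicSequence, GroundTruth]:
    """Generate one chromosome end (subtelomere + right-terminal telomere).

    Deterministic given ``config.seed``; returns the sequence and the full
    ground truth (boundary coordinate, per-unit variant events with
    tract-relative offsets, planted feature coordinates per track).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    tract, events = _simulate_telomere(config, rng)

    L = config.subtel_length
    # gc_skewed island blocks are negative controls (no CpG content), so
    # they are tracked separately from recoverable islands
    features: dict[str, list[tuple[int, int]]] = {
        "satellite": [],
        "island": [],
        "island_control": [],
        "g4": [],
        "motif": [],
    }
    if L > 0:
        subtel = bytearray(_background(L, config.gc_background, rng).tobytes())
        for unit, copies, off in config.satellite_blocks:
            block = unit * copies
            subtel[off : off + len(block)] = block.encode()
            features["satellite"].append((off, off + len(block)))
        for off, length, style in config.island_blocks:
            block = _island_block(length, style)
            subtel[off : off + length] = block.encode()
            track = "island" if style == "cpg_rich" else "island_control"
            features[track].append((off, off + length))
        for off, pattern in config.g4_inserts:
            subtel[off : off + len(pattern)] = pattern.encode()
            features["g4"].append((off, off + len(pattern)))
        for mid, off, strand in config.motif_placements:
            pat = _motif_pattern(mid)
            placed = pat if strand == "+" else reverse_complement(pat)
            subtel[off : off + len(pat)] = placed.encode()
            features["motif"].append((off, off + len(pat)))
        _scrub_boundary(subtel, config, rng)
        residues = subtel.decode() + tract
    else:
        residues = tract

    seq = GenomicSequence(f"sim_end_seed{config.seed}", residues)
    truth = GroundTruth(
        telomere_boundary=L,
        tract_length=len(tract),
        events=events,
        features=features,
        config=config,
    )
    return seq, truth


# ---------------------------------------------------------------------------
# recovery metrics


def _match_events(
    truth_events: Sequence[VariantEvent],
    found_events: Sequence[VariantEvent],
    tolerance: int = 1,
) -> int:
    """Greedy 1-1 matching by (kind, tract_offset +/- tolerance)."""
    matched = 0
    for kind in (SUBSTITUTION, ADDITION, DELETION):
        t = sorted(e.tract_offset for e in truth_events if e.kind == kind)
        f = sorted(e.tract_offset for e in found_events if e.kind == kind)
        i = j = 0
        while i < len(t) and j < len(f):
            if abs(t[i] - f[j]) <= tolerance:
                matched += 1
                i += 1
                j += 1
            elif f[j] < t[i]:
                j += 1
            else:
                i += 1
    return matched


def _interval_recall(
    planted: Sequence[tuple[int, int]],
    found: Sequence[tuple[int, int]],
    min_overlap_frac: float = 0.5,
) -> float:
    if not planted:
        return float("nan")
    hit = 0
    for s, e in planted:
        need = min_overlap_frac * (e - s)
        if any(min(e, fe) - max(s, fs) >= need for fs, fe in found):
            hit += 1
    return hit / len(planted)


def recovery_report(
    truth: GroundTruth,
    *,
    tract_start: int | None = None,
    events: Sequence[VariantEvent] | None = None,
    g4_intervals: Sequence[tuple[int, int]] | None = None,
    island_intervals: Sequence[tuple[int, int]] | None = None,
    motif_intervals: Sequence[tuple[int, int]] | None = None,
    offset_tolerance: int = 1,
) -> dict:
    """Compare pipeline outputs against the simulator's ground truth.

    Detected event offsets are taken relative to the detected tract start
    (``tract_start``, global coordinate); they are shifted into the truth
    frame before matching. Interval arguments are global coordinates.
    """
    report: dict = {}
    if tract_start is not None:
        report["boundary_error_bp"] = tract_start - truth.telomere_boundary
    if events is not None:
        delta = (
            (tract_start - truth.telomere_boundary)
            if tract_start is not None
            else 0
        )
        shifted = [
            replace(e, tract_offset=e.tract_offset + delta) for e in events
        ]
        matched = _match_events(truth.events, shifted, offset_tolerance)
        n_truth, n_found = len(truth.events), len(shifted)
        report["event_recall"] = matched / n_truth if n_truth else 1.0
        report["event_precision"] = matched / n_found if n_found else 1.0
        L = truth.tract_length
        for kind in (SUBSTITUTION, ADDITION, DELETION):
            t = sum(1 for e in truth.events if e.kind == kind)
            f = sum(1 for e in shifted if e.kind == kind)
            report[f"percent_{kind}_truth"] = 100.0 * t / L
            report[f"percent_{kind}_found"] = 100.0 * f / L
            report[f"percent_{kind}_delta"] = 100.0 * (f - t) / L
    for name, found in (
        ("g4", g4_intervals),
        ("island", island_intervals),
        ("motif", motif_intervals),
    ):
        if found is not None:
            report[f"{name}_recall"] = _interval_recall(
                truth.features.get(name, []), found
            )
    return report
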