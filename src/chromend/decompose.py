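"""Decomposition of a telomere tract into canonical repeat units.

The tract is aligned against a tandem array of the consensus unit
(``TTTAGGG`` by default) by wraparound dynamic programming: the alignment
column cycles over consensus positions so the optimum is taken over every
unit count simultaneously. Unit costs are 1 for substitution, insertion
(an *addition* to the tract) and deletion, 0 for a match; the minimal total
cost therefore equals the minimum over k of the plain edit distance between
the tract and ``consensus * k``, which is the property the test-suite oracle
checks.

Every optimal-path edit is emitted as a single-base :class:`VariantEvent`;
multi-base indels become runs of single-base events at consecutive offsets.
Among co-optimal alignments the traceback is deterministic: substitutions
are preferred over insertion+deletion pairs (automatic, by cost) and indels
are placed leftmost within homopolymer runs, so a deletion of one T in TTT
is always reported at the first T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


SUBSTITUTION = "substitution"
ADDITION = "addition"
DELETION = "deletion"


@dataclass(frozen=True)
class VariantEvent:
    """One classified single-base deviation from the consensus array.

    ``tract_offset`` is 0-based within the tract; for a deletion it is the
    offset of the base *following* the deleted consensus position.
    ``unit_position`` indexes the affected consensus base (0-6 for TTTAGGG);
    for additions it is the consensus position before which the base was
    inserted, with ``len(consensus)`` meaning "after the unit end".
    """

    kind: str
    tract_offset: int
    ref_base: str | None
    obs_base: str | None
    unit_index: int
    unit_position: int

    def __post_init__(self) -> None:
        if self.kind == SUBSTITUTION:
            if self.ref_base is None or self.obs_base is None:
                raise ValueError("substitution needs ref_base and obs_base")
            if self.ref_base == self.obs_base:
                raise ValueError("substitution with ref_base == obs_base")
        elif self.kind == ADDITION:
            if self.obs_base is None or self.ref_base is not None:
                raise ValueError("addition carries obs_base only")
        elif self.kind == DELETION:
            if self.ref_base is None or self.obs_base is not None:
                raise ValueError("deletion carries ref_base only")
        else:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class UnitRecord:
    """One consensus unit of the decomposition and the edits inside it."""

    unit_index: int
    start: int  # tract offsets, half-open span
    end: int
    edit_ops: list[VariantEvent] = field(default_factory=list)
    partial: bool = False


@dataclass
class UnitDecomposition:
    tract: str
    consensus: str
    units: list[UnitRecord]
    total_cost: int

    @property
    def events(self) -> list[VariantEvent]:
        return [ev for u in self.units for ev in u.edit_ops]


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _dp_py(tract: np.ndarray, cons: np.ndarray, free_start: bool) -> np.ndarray:
    n, m = tract.size, cons.size
    cost = np.empty((n + 1, m), dtype=np.int32)
    for j in range(m):
        cost[0, j] = 0 if free_start else j
    for i in range(1, n + 1):
        c = tract[i - 1]
        for j in range(m):
            pj = m - 1 if j == 0 else j - 1
            d = cost[i - 1, pj] + (0 if c == cons[pj] else 1)
            e = cost[i - 1, j] + 1
            cost[i, j] = d if d < e else e
        # cyclic within-row deletion relaxation; two passes suffice since a
        # full extra lap costs m >= 2 and can never win
        for _ in range(2):
            for j in range(m):
                pj = m - 1 if j == 0 else j - 1
                v = cost[i, pj] + 1
                if v < cost[i, j]:
                    cost[i, j] = v
    return cost


if _HAVE_NUMBA:
    _dp_numba = njit(cache=True)(_dp_py)
else:  # pragma: no cover
    _dp_numba = _dp_py


def _wraparound_cost(tract: str, consensus: str, free_start: bool) -> np.ndarray:
    t = _encode(tract)
    c = _encode(consensus)
    return _dp_numba(t, c, free_start)


def decompose(
    tract: str, consensus: str = "TTTAGGG", free_start: bool = False
) -> UnitDecomposition:
    """Align ``tract`` against the infinitely repeated ``consensus``.

    By default both tract ends are anchored at unit boundaries, so
    ``total_cost`` is the minimum over all unit counts k of the edit distance
    to ``consensus * k`` (k = 0 included, which only matters for tracts much
    shorter than one unit). With ``free_start=True`` the first unit may begin
    mid-consensus without charge; it is flagged partial and its span carries
    no boundary-deletion events, which suits tracts whose interior edge was
    cut mid-unit by the telomere detector.
    """
    if not tract:
        raise ValueError("tract must be non-empty")
    if len(consensus) < 2:
        raise ValueError("consensus must be at least 2 bp")
    m = len(consensus)
    cost = _wraparound_cost(tract, consensus, free_start)
    n = len(tract)
    total = int(cost[n, 0])

    # --- traceback (prefer diag > del > ins: leftmost indels forward) ---
    C = cost.tolist()
    path: list[str] = []  # ops collected terminal-to-start
    i, j = n, 0
    while True:
        if i == 0 and (j == 0 or free_start):
            break
        pj = m - 1 if j == 0 else j - 1
        cur = C[i][j]
        if i > 0:
            sub = 0 if tract[i - 1] == consensus[pj] else 1
            if C[i - 1][pj] + sub == cur:
                path.append("S" if sub else "M")
                i -= 1
                j = pj
                continue
        if C[i][pj] + 1 == cur:
            path.append("D")
            j = pj
            continue
        path.append("I")
        i -= 1
    path.reverse()
    start_j = j  # non-zero only with free_start

    # --- forward replay: assign events and unit spans ---
    units: list[UnitRecord] = []
    events_total = 0
    i = 0
    j = start_j
    unit_idx = 0
    unit_start = 0
    cur = UnitRecord(unit_idx, 0, 0, partial=(start_j != 0))

    def close_unit(end: int) -> None:
        nonlocal cur, unit_idx
        cur.end = end
        units.append(cur)
        unit_idx += 1
        cur = UnitRecord(unit_idx, end, end)

    for op in path:
        if op in ("M", "S"):
            if op == "S":
                cur.edit_ops.append(
                    VariantEvent(
                        SUBSTITUTION, i, consensus[j], tract[i], unit_idx, j
                    )
                )
                events_total += 1
            i += 1
            j += 1
        elif op == "D":
            # offset of the base following the deleted position (== n when
            # the deletion falls at the very end of the tract)
            cur.edit_ops.append(
                VariantEvent(DELETION, i, consensus[j], None, unit_idx, j)
            )
            events_total += 1
            j += 1
        else:  # insertion = addition to the tract
            if j == 0 and units:
                prev = units[-1]
                prev.edit_ops.append(
                    VariantEvent(ADDITION, i, None, tract[i], prev.unit_index, m)
                )
                prev.end = i + 1
                events_total += 1
                i += 1
                cur.start = i
                cur.end = i
                continue
            cur.edit_ops.append(
                VariantEvent(ADDITION, i, None, tract[i], unit_idx, j)
            )
            events_total += 1
            i += 1
        if j == m:
            close_unit(i)
            j = 0
    if cur.edit_ops or cur.start != i or j != 0:
        # trailing partial state should not occur with an anchored end
        cur.end = i
        units.append(cur)

    deco = UnitDecomposition(tract, consensus, units, total)
    if not free_start and events_total != total:  # pragma: no cover - sanity
        raise AssertionError(
            f"traceback emitted {events_total} events for cost {total}"
        )
    return deco


def classify_variants(d: UnitDecomposition) -> list[VariantEvent]:
    """Flatten a decomposition into tract-offset-sorted events.

    Events inside partial boundary units (``free_start`` mode) are excluded:
    they describe the arbitrary cut point of the tract, not the repeat array.
    """
    kind_rank = {SUBSTITUTION: 0, DELETION: 1, ADDITION: 2}
    evs = [
        ev
        for u in d.units
        if not u.partial
        for ev in u.edit_ops
    ]
    return sorted(evs, key=lambda e: (e.tract_offset, kind_rank[e.kind]))


@dataclass
class VariantSummary:
    """Per-tract event statistics in the layout of the published tables.

    Percentages use the observed tract length in bp as denominator by
    default (``denominator='units'`` divides by the unit count instead);
    ``percent_all`` is the exact arithmetic sum of the three.
    """

    tract_length: int
    counts: dict[str, int]
    percent: dict[str, float]
    percent_all: float
    base_breakdown: dict[str, dict[str, float]]
    positional_histogram: np.ndarray
    bin: int
    events: list[VariantEvent] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "kind": [SUBSTITUTION, ADDITION, DELETION, "all"],
                "count": [
                    self.counts[SUBSTITUTION],
                    self.counts[ADDITION],
                    self.counts[DELETION],
                    sum(self.counts.values()),
                ],
                "percent": [
                    self.percent[SUBSTITUTION],
                    self.percent[ADDITION],
                    self.percent[DELETION],
                    self.percent_all,
                ],
            }
        )


def summarize(
    events: Sequence[VariantEvent],
    tract_length: int,
    bin: int = 100,
    denominator: str = "bp",
    unit_length: int = 7,
) -> VariantSummary:
    """Count events by kind and produce percentages, base biases and a
    positional histogram over ``[0, tract_length)`` in ``bin``-bp bins."""
    if tract_length <= 0:
        raise ValueError("tract_length must be > 0")
    if denominator not in ("bp", "units"):
        raise ValueError("denominator must be 'bp' or 'units'")
    counts = {SUBSTITUTION: 0, ADDITION: 0, DELETION: 0}
    by_base: dict[str, dict[str, int]] = {
        SUBSTITUTION: {},
        ADDITION: {},
        DELETION: {},
    }
    nbins = max(1, math.ceil(tract_length / bin))
    hist = np.zeros(nbins, dtype=np.int64)
    for ev in events:
        counts[ev.kind] += 1
        base = ev.obs_base if ev.kind == ADDITION else ev.ref_base
        by_base[ev.kind][base] = by_base[ev.kind].get(base, 0) + 1
        b = min(ev.tract_offset // bin, nbins - 1)
        hist[b] += 1
    denom = tract_length if denominator == "bp" else tract_length / unit_length
    percent = {k: 100.0 * v / denom for k, v in counts.items()}
    percent_all = (
        percent[SUBSTITUTION] + percent[ADDITION] + percent[DELETION]
    )
    breakdown = {
        k: {b: c / counts[k] for b, c in v.items()} if counts[k] else {}
        for k, v in by_base.items()
    }
    return VariantSummary(
        tract_length=tract_length,
        counts=counts,
        percent=percent,
        percent_all=percent_all,
        base_breakdown=breakdown,
        positional_histogram=hist,
        bin=bin,
        events=list(events),
    )


def positional_enrichment(
    summary: VariantSummary, edge_fraction: float = 0.1
) -> float:
    """Ratio of event density in the two terminal edge segments to the
    density in the interior; ``inf`` when the interior is event-free but the
    edges are not, ``nan`` when there are no events at all."""
    L = summary.tract_length
    if L <= 0:
        raise ValueError("tract_length must be > 0")
    e = max(1, int(round(edge_fraction * L)))
    if 2 * e >= L:
        raise ValueError("edge_fraction leaves no interior")
    edge_n = sum(
        1
        for ev in summary.events
        if ev.tract_offset < e or ev.tract_offset >= L - e
    )
    interior_n = len(summary.events) - edge_n
    edge_density = edge_n / (2 * e)
    interior_density = interior_n / (L - 2 * e)
    if interior_n == 0:
        return math.inf if edge_n > 0 else math.nan
    return edge_density / interior_density
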