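"""Terminal telomere tract detection and subtelomere panel definition.

A chromosome end is scanned for a maximal terminal interval of
canonical-or-1-edit telomere units (``TTTAGGG`` on the G-strand, ``CCCTAAA``
on the C-strand). "1-edit" means any 6-8 bp substring within edit distance
one of the unit; telomeres carry single-base variants throughout, so exact
matching would truncate tracts. The tract must begin at the terminus, may
contain no internal run of non-telomeric bases longer than
``max_interruption``, must keep an overall purity (fraction of bases inside
recognized units) of at least ``purity_min``, and must contain at least
``min_units`` recognized units.

Detection on the left end is performed by reflecting the problem: the
sequence is reverse-complemented, scanned on the right, and coordinates and
orientation are mirrored back, which makes the left/right symmetry exact by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

from .seqio import GenomicSequence, Region, reverse_complement

log = logging.getLogger(__name__)

PLANT_TELOMERE_UNIT = "TTTAGGG"

G_STRAND = "G-strand"
C_STRAND = "C-strand"


@dataclass(frozen=True)
class TelomereTract:
    """A detected terminal telomeric repeat tract."""

    region: Region
    orientation: str  # G-strand (TTTAGGG on +) or C-strand (CCCTAAA on +)
    unit_estimate: int
    purity: float
    side: str  # which terminus was searched


@dataclass(frozen=True)
class Panel:
    """A named subtelomere analysis window."""

    name: str
    region: Region
    clipped: bool = False


@lru_cache(maxsize=8)
def _one_edit_neighborhood(unit: str) -> tuple[frozenset, ...]:
    """All strings within edit distance 1 of ``unit``, keyed by length."""
    bases = "ACGT"
    m = len(unit)
    by_len: dict[int, set[str]] = {m - 1: set(), m: {unit}, m + 1: set()}
    for p in range(m):
        by_len[m - 1].add(unit[:p] + unit[p + 1 :])
        for b in bases:
            if b != unit[p]:
                by_len[m].add(unit[:p] + b + unit[p + 1 :])
    # insertion variants only at internal positions: a string producible
    # solely by a terminal insertion (e.g. unit + one arbitrary base) would
    # let a tract swallow one neighbouring non-telomeric base at every
    # boundary, making the detected edge systematically fuzzy
    for p in range(1, m):
        for b in bases:
            by_len[m + 1].add(unit[:p] + b + unit[p:])
    return tuple(frozenset(by_len[L]) for L in (m - 1, m, m + 1))


def _coverage(residues: str, unit: str) -> bytearray:
    """Mark every base lying inside a canonical-or-1-edit unit occurrence."""
    n = len(residues)
    m = len(unit)
    nbs = _one_edit_neighborhood(unit)
    lengths = (m - 1, m, m + 1)
    cov = bytearray(n)
    ones = {L: b"\x01" * L for L in lengths}
    for L, nb in zip(lengths, nbs):
        for s in range(n - L + 1):
            if residues[s : s + L] in nb:
                cov[s : s + L] = ones[L]
    return cov


def _scan_right(
    residues: str,
    unit: str,
    min_units: int,
    purity_min: float,
    max_interruption: int,
) -> tuple[int, int] | None:
    """Maximal right-terminal tract for one orientation.

    Returns ``(start, covered_bases)`` of the best (longest) qualifying
    interval ``[start, len)``, or ``None``.
    """
    cov = _coverage(residues, unit)
    n = len(residues)
    m = len(unit)
    covered = 0
    run_uncov = 0
    best: tuple[int, int] | None = None
    for i in range(n - 1, -1, -1):
        if cov[i]:
            covered += 1
            run_uncov = 0
            tract_len = n - i
            purity = covered / tract_len
            if purity >= purity_min and covered // m >= min_units:
                best = (i, covered)
        else:
            run_uncov += 1
            if run_uncov > max_interruption:
                break
    return best


def detect_telomere(
    end_seq: GenomicSequence,
    side: str,
    min_units: int = 5,
    purity_min: float = 0.8,
    max_interruption: int = 21,
    consensus: str = PLANT_TELOMERE_UNIT,
) -> TelomereTract | None:
    """Detect the terminal telomeric tract on one side of ``end_seq``.

    Absence is a value (``None``), not an error. Orientation is chosen by
    whichever unit (G- vs C-strand) yields the higher purity; on a tie the
    orientation conventional for the searched side wins (G-strand at the
    right end, C-strand at the left).
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    residues = end_seq.residues
    n = len(residues)
    if side == "left":
        mirror = detect_telomere(
            GenomicSequence(end_seq.id, reverse_complement(residues)),
            "right",
            min_units=min_units,
            purity_min=purity_min,
            max_interruption=max_interruption,
            consensus=consensus,
        )
        if mirror is None:
            return None
        r = mirror.region
        return TelomereTract(
            region=Region(end_seq.id, n - r.end, n - r.start, "+"),
            orientation=C_STRAND if mirror.orientation == G_STRAND else G_STRAND,
            unit_estimate=mirror.unit_estimate,
            purity=mirror.purity,
            side="left",
        )

    g_unit = consensus
    c_unit = reverse_complement(consensus)
    cand_g = _scan_right(residues, g_unit, min_units, purity_min, max_interruption)
    cand_c = _scan_right(residues, c_unit, min_units, purity_min, max_interruption)
    if cand_g is None and cand_c is None:
        return None

    def purity_of(cand):
        start, covered = cand
        return covered / (n - start)

    if cand_c is None or (
        cand_g is not None and purity_of(cand_g) >= purity_of(cand_c)
    ):
        start, covered = cand_g
        orientation = G_STRAND
    else:
        start, covered = cand_c
        orientation = C_STRAND
    length = n - start
    return TelomereTract(
        region=Region(end_seq.id, start, n, "+"),
        orientation=orientation,
        unit_estimate=round(length / len(consensus)),
        purity=covered / length,
        side="right",
    )


def subtelomere_panels(
    chrom: GenomicSequence,
    tract: TelomereTract,
    panel: int = 500_000,
    extended: int = 5_000_000,
    offsets: tuple[int, ...] = (5_000_000, 50_000_000),
) -> list[Panel]:
    """Define the subtelomere comparison windows interior to the tract.

    Returns the distal subtelomere (``panel`` bp immediately interior to the
    tract boundary), the extended subtelomere (``extended`` bp interior), and
    for each offset ``d`` a ``panel``-bp window whose distal edge lies ``d``
    bp interior to the first base of the telomere. Windows running past the
    chromosome start are clipped and flagged; a window falling entirely
    outside is omitted with a warning.
    """
    panels: list[Panel] = []
    n = chrom.length

    if tract.side == "right":
        boundary = tract.region.start  # first base of the telomere

        def window(dist_edge: int, width: int) -> tuple[int, int]:
            return dist_edge - width, dist_edge

    else:
        boundary = tract.region.end

        def window(dist_edge: int, width: int) -> tuple[int, int]:
            # mirror: interior lies to the right of a left-end telomere
            a = n - dist_edge  # reflected coordinate of the distal edge
            return a, a + width

        boundary = n - boundary  # distance-from-interior form for reuse

    def add(name: str, dist_edge: int, width: int) -> None:
        a, b = window(dist_edge, width)
        clipped = False
        if a < 0:
            a, clipped = 0, True
        if b > n:
            b, clipped = n, True
        if b <= a:
            log.warning("panel %s lies entirely outside the sequence; omitted", name)
            return
        panels.append(Panel(name, Region(chrom.id, a, b, "+"), clipped))

    add("distal", boundary, panel)
    add("extended", boundary, extended)
    for d in offsets:
        add(f"offset_{d}", boundary - d, panel)
    return panels
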