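"""Fixed-string and base-run motif scanning on both strands.

Six built-in motifs are provided: three short sequences associated with
recombination hotspots (the simple repeat CCGCCGCCG and the
transposon-associated CTCCCTCC and TTAGTCCCGGTT) and three protein-binding
site patterns (SMC1-beta cohesin CCACCAGGTGGC, YY1 GGGGGCAGTGG, and
HMG-protein A/T runs longer than 5 bp).

Matching is exact by default; occurrences may overlap and all are reported.
Minus-strand hits are found by matching the reverse complement of the
pattern against the + strand and are reported in + strand coordinates; a
pattern equal to its own reverse complement is reported once, on +. An
optional Hamming-distance mode (``max_mismatch``) exists for sensitivity
analysis of the short fixed patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import Region, reverse_complement

HOTSPOT = "hotspot"
PROTEIN_SITE = "protein_site"


@dataclass(frozen=True)
class Motif:
    id: str
    source: str
    pattern: str | None = None  # fixed-string motif
    run_alphabet: frozenset | None = None  # run-spec motif
    min_len_exclusive: int | None = None

    def __post_init__(self) -> None:
        if self.pattern is not None:
            if len(self.pattern) < 4:
                raise ValueError("fixed pattern must be >= 4 bp")
        elif self.run_alphabet is not None:
            if self.min_len_exclusive is None or self.min_len_exclusive < 1:
                raise ValueError("run-spec needs min_len_exclusive >= 1")
        else:
            raise ValueError("motif needs a pattern or a run spec")

    @property
    def is_run(self) -> bool:
        return self.run_alphabet is not None


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    region: Region
    strand: str
    matched: str  # + strand residues at the hit


def builtin_motifs() -> list[Motif]:
    """The six motifs scanned by default."""
    return [
        Motif("CCGCCGCCG", HOTSPOT, pattern="CCGCCGCCG"),
        Motif("CTCCCTCC", HOTSPOT, pattern="CTCCCTCC"),
        Motif("TTAGTCCCGGTT", HOTSPOT, pattern="TTAGTCCCGGTT"),
        Motif("SMC1B", PROTEIN_SITE, pattern="CCACCAGGTGGC"),
        Motif("YY1", PROTEIN_SITE, pattern="GGGGGCAGTGG"),
        Motif(
            "HMG_AT_run",
            PROTEIN_SITE,
            run_alphabet=frozenset("AT"),
            min_len_exclusive=5,
        ),
    ]


def _find_exact(seq: str, pattern: str) -> list[int]:
    out = []
    i = seq.find(pattern)
    while i != -1:
        out.append(i)
        i = seq.find(pattern, i + 1)  # overlapping occurrences included
    return out


def _find_hamming(seq: str, pattern: str, max_mismatch: int) -> list[int]:
    n, m = len(seq), len(pattern)
    if n < m:
        return []
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mism = np.zeros(n - m + 1, dtype=np.int32)
    for k, ch in enumerate(pattern.encode("ascii")):
        mism += a[k : n - m + 1 + k] != ch
    return [int(i) for i in np.flatnonzero(mism <= max_mismatch)]


def scan_fixed(
    seq: str,
    motif: Motif,
    both_strands: bool = True,
    max_mismatch: int = 0,
    seq_id: str = "seq",
) -> list[MotifHit]:
    """All occurrences of a fixed-pattern motif, overlapping included."""
    if motif.pattern is None:
        raise ValueError(f"motif {motif.id!r} is not a fixed-pattern motif")
    pat = motif.pattern
    finder = (
        (lambda s, p: _find_exact(s, p))
        if max_mismatch == 0
        else (lambda s, p: _find_hamming(s, p, max_mismatch))
    )
    hits = [
        MotifHit(motif.id, Region(seq_id, i, i + len(pat), "+"), "+", pat)
        for i in finder(seq, pat)
    ]
    rc = reverse_complement(pat)
    if both_strands and rc != pat:  # palindrome: report once, on +
        hits += [
            MotifHit(motif.id, Region(seq_id, i, i + len(rc), "-"), "-", rc)
            for i in finder(seq, rc)
        ]
    hits.sort(key=lambda h: (h.region.start, h.strand))
    return hits


def scan_runs(
    seq: str,
    alphabet: frozenset | set = frozenset("AT"),
    min_len_exclusive: int = 5,
    motif_id: str = "HMG_AT_run",
    seq_id: str = "seq",
) -> list[MotifHit]:
    """Maximal runs of bases from ``alphabet`` strictly longer than
    ``min_len_exclusive``; reported on + (A/T runs are strand-symmetric)."""
    alphabet = frozenset(alphabet)
    hits = []
    start = None
    for i, ch in enumerate(seq):
        if ch in alphabet:
            if start is None:
                start = i
        else:
            if start is not None and i - start > min_len_exclusive:
                hits.append(
                    MotifHit(
                        motif_id, Region(seq_id, start, i, "+"), "+", seq[start:i]
                    )
                )
            start = None
    if start is not None and len(seq) - start > min_len_exclusive:
        hits.append(
            MotifHit(
                motif_id, Region(seq_id, start, len(seq), "+"), "+", seq[start:]
            )
        )
    return hits


def scan_all(
    seq: str,
    motifs: list[Motif] | None = None,
    both_strands: bool = True,
    max_mismatch: int = 0,
    seq_id: str = "seq",
) -> dict[str, list[MotifHit]]:
    """Scan every motif (built-ins by default); one hit list per motif id."""
    if motifs is None:
        motifs = builtin_motifs()
    out: dict[str, list[MotifHit]] = {}
    for m in motifs:
        if m.is_run:
            out[m.id] = scan_runs(
                seq,
                m.run_alphabet,
                m.min_len_exclusive,
                motif_id=m.id,
                seq_id=seq_id,
            )
        else:
            out[m.id] = scan_fixed(
                seq, m, both_strands=both_strands, max_mismatch=max_mismatch,
                seq_id=seq_id,
            )
    return out
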