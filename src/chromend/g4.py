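"""G-quadruplex propensity scanning with a run-capped base score.

Each base inside a maximal G-run of length L scores ``+min(L, 4)``; bases in
C-runs score ``-min(L, 4)``; A, T and N score 0. A sliding window (default
25 bp, step 1) qualifies when the absolute window mean reaches the
threshold; overlapping or adjacent qualifying windows of the same sign are
merged into one candidate interval, trimmed so it starts and ends on a base
of the enriched letter. The threshold default of 1.8 is the restrictive
setting; 1.2 is the permissive standard.

The sign convention: positive scores mean a G-rich (``+``) quadruplex on the
scanned strand, negative a C-rich one, i.e. a quadruplex on the complement
(``-``). Scanning the reverse complement yields exactly the mirrored hits
with signs flipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import groupby

import numpy as np

from .seqio import Region

log = logging.getLogger(__name__)

MAX_RUN_SCORE = 4


@dataclass(frozen=True)
class G4Hit:
    region: Region
    strand_sign: str  # '+' G-rich, '-' C-rich
    max_window_score: float  # signed extreme window mean
    mean_score: float  # mean base score over the trimmed interval
    short: bool = False  # trimmed below one window length


@dataclass
class G4Profile:
    hits: list[G4Hit]
    scanned_length: int
    dropped_n: int = 0  # candidates discarded for >10% N content

    @property
    def frequency(self) -> float:
        """Hits per 1000 bp (exact identity with count and length)."""
        if self.scanned_length <= 0:
            raise ValueError("scanned_length must be > 0")
        return 1000.0 * len(self.hits) / self.scanned_length


def base_scores(seq: str) -> np.ndarray:
    """Per-base G4 propensity scores (run-capped at +/-4)."""
    scores = np.zeros(len(seq), dtype=np.float64)
    pos = 0
    for base, grp in groupby(seq):
        run = sum(1 for _ in grp)
        if base == "G":
            scores[pos : pos + run] = min(run, MAX_RUN_SCORE)
        elif base == "C":
            scores[pos : pos + run] = -min(run, MAX_RUN_SCORE)
        pos += run
    return scores


_EPS = 1e-9


def find_g4(
    seq: str,
    window: int = 25,
    threshold: float = 1.8,
    merge: bool = True,
    seq_id: str = "seq",
) -> G4Profile:
    """Scan ``seq`` and return above-threshold quadruplex candidates.

    With ``merge=False`` every qualifying window becomes its own (untrimmed)
    hit, which makes the profile count raw windows instead of merged
    intervals. Candidates whose span contains more than 10% N are dropped
    and logged.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    n = len(seq)
    if n < window:
        return G4Profile(hits=[], scanned_length=n)
    scores = base_scores(seq)
    kernel = np.ones(window)
    means = np.convolve(scores, kernel, mode="valid") / window
    plus = means >= threshold - _EPS
    minus = means <= -(threshold - _EPS)

    is_n = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord("N")
    n_cum = np.concatenate(([0], np.cumsum(is_n)))

    hits: list[G4Hit] = []
    dropped = 0

    def n_fraction(a: int, b: int) -> float:
        return (n_cum[b] - n_cum[a]) / (b - a)

    def emit(first_s: int, last_s: int, sign: str) -> None:
        nonlocal dropped
        a, b = first_s, last_s + window
        if n_fraction(a, b) > 0.10:
            dropped += 1
            log.info("dropped %s G4 candidate [%d, %d): >10%% N", sign, a, b)
            return
        letter = "G" if sign == "+" else "C"
        while a < b and seq[a] != letter:
            a += 1
        while b > a and seq[b - 1] != letter:
            b -= 1
        if b <= a:
            dropped += 1
            return
        member = means[first_s : last_s + 1]
        extreme = float(member.max() if sign == "+" else member.min())
        hits.append(
            G4Hit(
                region=Region(seq_id, a, b, "+"),
                strand_sign=sign,
                max_window_score=extreme,
                mean_score=float(scores[a:b].mean()),
                short=(b - a) < window,
            )
        )

    for sign, mask in (("+", plus), ("-", minus)):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        if not merge:
            for s in idx:
                s = int(s)
                if n_fraction(s, s + window) > 0.10:
                    dropped += 1
                    continue
                hits.append(
                    G4Hit(
                        region=Region(seq_id, s, s + window, "+"),
                        strand_sign=sign,
                        max_window_score=float(means[s]),
                        mean_score=float(means[s]),
                    )
                )
            continue
        # merge overlapping or abutting qualifying windows of the same sign
        first = int(idx[0])
        prev = first
        for s in idx[1:]:
            s = int(s)
            if s <= prev + window:
                prev = s
            else:
                emit(first, prev, sign)
                first = prev = s
        emit(first, prev, sign)

    hits.sort(key=lambda h: (h.region.start, h.strand_sign))
    return G4Profile(hits=hits, scanned_length=n, dropped_n=dropped)


def g4_frequency(profile: G4Profile) -> float:
    """Hits per 1000 bp of scanned sequence (tables round to 2 decimals)."""
    return profile.frequency
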