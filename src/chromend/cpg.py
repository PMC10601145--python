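"""Windowed GC content and CpG-island prediction.

The island caller follows the classic cpgplot procedure: %GC and the
observed/expected CpG ratio are computed in 100-bp windows shifted by 1 bp;
a running average over 10 consecutive windows must reach 50% GC and an
observed/expected ratio of 0.6 before a position qualifies, and maximal
qualified runs at least 200 bp long are reported as islands. The
observed/expected ratio of a window is

    (count of CG dinucleotides x window length) / (count C x count G)

defined as 0 when the window lacks C or G entirely. Positions whose
averaging span would run past the sequence end are never qualified (no
padding is invented), and windows with more than 10% N are unqualified and
flagged, so unsequenced gaps break islands rather than bridging them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import Region

_EPS = 1e-9


@dataclass
class GCProfile:
    """Per-start %GC values for sliding windows (step 1)."""

    window: int
    values: np.ndarray  # percent, one value per window start
    step: int = 1
    n_flagged: np.ndarray | None = None  # windows with >10% N


@dataclass(frozen=True)
class CpGIsland:
    region: Region
    mean_oe: float
    mean_gc: float  # percent


def _indicator_cumsums(seq: str):
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = a == ord("C")
    is_g = a == ord("G")
    is_n = a == ord("N")
    is_cg = is_c[:-1] & is_g[1:] if len(seq) > 1 else np.zeros(0, dtype=bool)
    cum = lambda x: np.concatenate(([0], np.cumsum(x, dtype=np.int64)))
    return cum(is_c), cum(is_g), cum(is_n), cum(is_cg)


def gc_profile(seq: str, window: int = 100) -> GCProfile:
    """%GC per window start; N bases are excluded from both numerator and
    denominator, and windows with >10% N are flagged."""
    n = len(seq)
    if n < window:
        raise ValueError(f"sequence ({n} bp) shorter than window ({window} bp)")
    c_cum, g_cum, n_cum, _ = _indicator_cumsums(seq)
    starts = np.arange(n - window + 1)
    gc = (c_cum[starts + window] - c_cum[starts]) + (
        g_cum[starts + window] - g_cum[starts]
    )
    nn = n_cum[starts + window] - n_cum[starts]
    denom = window - nn
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, 100.0 * gc / np.maximum(denom, 1), 0.0)
    flagged = nn > 0.10 * window
    return GCProfile(window=window, values=vals, n_flagged=flagged)


def obs_exp_cpg(window_seq: str) -> float:
    """Observed/expected CpG ratio of one window; 0 when C or G is absent."""
    if len(window_seq) < 2:
        raise ValueError("window must be at least 2 bp")
    c = window_seq.count("C")
    g = window_seq.count("G")
    if c == 0 or g == 0:
        return 0.0
    cg = window_seq.count("CG")
    return cg * len(window_seq) / (c * g)


def find_islands(
    seq: str,
    window: int = 100,
    min_len: int = 200,
    min_oe: float = 0.6,
    min_gc: float = 50.0,
    avg_windows: int = 10,
    seq_id: str = "seq",
) -> list[CpGIsland]:
    """Predict CpG islands; see the module docstring for the procedure.

    Reported ``mean_gc``/``mean_oe`` are means of the averaged window
    statistics over the island's qualified positions, so they satisfy the
    qualification thresholds by construction.
    """
    n = len(seq)
    if n < window * avg_windows:
        raise ValueError(
            f"sequence ({n} bp) shorter than window*avg_windows "
            f"({window * avg_windows} bp)"
        )
    c_cum, g_cum, n_cum, cg_cum = _indicator_cumsums(seq)
    S = n - window + 1
    starts = np.arange(S)
    c = c_cum[starts + window] - c_cum[starts]
    g = g_cum[starts + window] - g_cum[starts]
    nn = n_cum[starts + window] - n_cum[starts]
    # CG dinucleotides fully inside the window: start positions [s, s+w-1)
    cg = cg_cum[starts + window - 1] - cg_cum[starts]
    win_gc = 100.0 * (c + g) / window
    with np.errstate(invalid="ignore", divide="ignore"):
        win_oe = np.where((c > 0) & (g > 0), cg * window / np.maximum(c * g, 1), 0.0)
    ok = nn <= 0.10 * window

    A = S - avg_windows + 1  # positions with a full averaging span
    if A <= 0:
        return []
    kernel = np.ones(avg_windows)
    avg_gc = np.convolve(win_gc, kernel, mode="valid") / avg_windows
    avg_oe = np.convolve(win_oe, kernel, mode="valid") / avg_windows
    all_ok = np.convolve(ok.astype(int), kernel, mode="valid") == avg_windows
    qualified = (
        (avg_gc >= min_gc - _EPS) & (avg_oe >= min_oe - _EPS) & all_ok
    )

    islands: list[CpGIsland] = []
    idx = np.flatnonzero(qualified)
    if idx.size == 0:
        return islands
    run_start = int(idx[0])
    prev = run_start
    runs = []
    for s in idx[1:]:
        s = int(s)
        if s == prev + 1:
            prev = s
        else:
            runs.append((run_start, prev))
            run_start = prev = s
    runs.append((run_start, prev))
    for a, b in runs:
        start, end = a, b + window
        if end - start < min_len:
            continue
        islands.append(
            CpGIsland(
                region=Region(seq_id, start, end, "+"),
                mean_oe=float(avg_oe[a : b + 1].mean()),
                mean_gc=float(avg_gc[a : b + 1].mean()),
            )
        )
    return islands
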