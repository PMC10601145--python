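"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: the edit-distance oracle
is a textbook Wagner-Fischer table over explicit tandem arrays, and the G4
oracle enumerates every window and merges naively.
"""

from __future__ import annotations


def edit_distance(a: str, b: str) -> int:
    """Plain Wagner-Fischer edit distance, unit costs."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (ca != cb),
            )
        prev = cur
    return prev[-1]


def min_distance_to_tandem_array(tract: str, consensus: str) -> int:
    """Minimum over k >= 0 of edit_distance(tract, consensus * k).

    Searches k outward from len(tract)/len(consensus); a length-difference
    lower bound prunes hopeless k values, which keeps this exact.
    """
    n, m = len(tract), len(consensus)
    best = n  # k = 0: delete everything
    k0 = max(1, round(n / m))
    k = k0
    step = 0
    seen_up = seen_down = False
    while True:
        candidates = []
        for kk in (k0 + step, k0 - step):
            if kk >= 1 and abs(n - kk * m) <= best:
                candidates.append(kk)
        if not candidates and step > 0:
            lo_done = k0 - step < 1 or abs(n - (k0 - step) * m) > best
            hi_done = abs(n - (k0 + step) * m) > best
            if lo_done and hi_done:
                break
        for kk in set(candidates):
            best = min(best, edit_distance(tract, consensus * kk))
        step += 1
        if step > n + 2:  # safety net; never reached in practice
            break
    return best


def naive_g4_scan(
    seq: str, window: int = 25, threshold: float = 1.8
) -> list[tuple[int, int, str]]:
    """Enumerate every window, score it from scratch, merge adjacent
    same-sign qualifying windows, trim to the enriched letter, and drop
    spans with more than 10% N. Returns (start, end, sign) tuples."""
    n = len(seq)
    if n < window:
        return []

    def score(base_index: int) -> int:
        b = seq[base_index]
        if b not in "GC":
            return 0
        run = 1
        i = base_index
        while i > 0 and seq[i - 1] == b:
            run += 1
            i -= 1
        i = base_index
        while i < n - 1 and seq[i + 1] == b:
            run += 1
            i += 1
        return min(run, 4) if b == "G" else -min(run, 4)

    per_base = [score(i) for i in range(n)]
    qual = []  # (start, sign)
    for s in range(n - window + 1):
        mean = sum(per_base[s : s + window]) / window
        if mean >= threshold - 1e-9:
            qual.append((s, "+"))
        elif mean <= -(threshold - 1e-9):
            qual.append((s, "-"))
    merged = []
    for s, sign in qual:
        if merged and merged[-1][2] == sign and s <= merged[-1][1]:
            merged[-1][1] = s + window
        else:
            merged.append([s, s + window, sign])
    out = []
    for a, b, sign in merged:
        if seq[a:b].count("N") / (b - a) > 0.10:
            continue
        letter = "G" if sign == "+" else "C"
        while a < b and seq[a] != letter:
            a += 1
        while b > a and seq[b - 1] != letter:
            b -= 1
        if b > a:
            out.append((a, b, sign))
    out.sort()
    return out


def naive_motif_positions(seq: str, pattern: str) -> list[int]:
    """Position-by-position comparison, overlapping occurrences included."""
    m = len(pattern)
    return [
        i for i in range(len(seq) - m + 1) if seq[i : i + m] == pattern
    ]


def apply_unit_ops(consensus: str, unit) -> str:
    """Forward-apply one unit's edit ops to the consensus.

    Reconstructs the tract span the unit claims to explain; used to verify
    that a decomposition is internally consistent.
    """
    ops = sorted(
        unit.edit_ops,
        key=lambda e: (e.unit_position, 0 if e.kind == "deletion" else 1,
                       e.tract_offset),
    )
    s = list(consensus)
    for e in reversed(ops):
        p = e.unit_position
        if e.kind == "substitution":
            s[p] = e.obs_base
        elif e.kind == "deletion":
            del s[p]
        else:
            s.insert(p, e.obs_base)
    return "".join(s)


def random_tandem_mutant(rng, consensus: str, max_len: int = 70):
    """A tract derived from (consensus)^k by a few random point edits."""
    k = int(rng.integers(1, max_len // len(consensus) + 1))
    s = list(consensus * k)
    n_edits = int(rng.integers(0, 5))
    for _ in range(n_edits):
        if not s:
            break
        kind = rng.integers(3)
        pos = int(rng.integers(len(s)))
        base = "ACGT"[int(rng.integers(4))]
        if kind == 0:
            s[pos] = base
        elif kind == 1:
            s.insert(pos, base)
        else:
            del s[pos]
    return "".join(s) if s else consensus
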