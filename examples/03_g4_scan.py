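"""Scan telomere and subtelomere for G-quadruplex candidates.

Runs the run-capped window score over a simulated chromosome end at the
permissive (1.2) and restrictive (1.8) thresholds, separately for the
telomere tract and the subtelomere, and shows the recovery of a planted
quadruplex insert.
"""

from chromend import SimulationConfig, detect_telomere, find_g4, simulate_chromosome_end

cfg = SimulationConfig(
    seed=3,
    unit_count=1000,
    subtel_length=50_000,
    g4_inserts=((20_000, "GGGGTTGGGGTTGGGGTTGGGG"),),
)
seq, truth = simulate_chromosome_end(cfg)
tract = detect_telomere(seq, side="right")

telomere = seq.residues[tract.region.start :]
subtelomere = seq.residues[: tract.region.start]

for name, part in (("telomere", telomere), ("subtelomere", subtelomere)):
    for thr in (1.2, 1.8):
        prof = find_g4(part, window=25, threshold=thr)
        print(
            f"{name:12s} threshold={thr}  length={prof.scanned_length:>7,} bp  "
            f"hits={len(prof.hits):>3}  frequency={prof.frequency:.2f}/1000 bp"
        )

sub_prof = find_g4(subtelomere, threshold=1.8)
planted = [h for h in sub_prof.hits if h.region.start < 20_022 and h.region.end > 20_000]
print(f"\nplanted quadruplex recovered as {len(planted)} hit(s):")
for h in planted:
    print(f"  [{h.region.start:,}, {h.region.end:,}) sign {h.strand_sign} "
          f"max window mean {h.max_window_score:.2f}")
print()
print("A pure TTTAGGG array has a window mean near 1.29: above the 1.2")
print("threshold (the whole G-strand merges into one long hit) but below")
print("1.8, where only windows enriched by G-addition variants or planted")
print("G4 motifs qualify. That is what makes the restrictive threshold")
print("selective for distinctive quadruplex-forming sites.")
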