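"""Motif scanning and region-panel density comparison.

Scans the six built-in motifs (three hotspot-associated sequences, two
protein-binding sites, and A/T runs for HMG proteins) over a simulated
subtelomere, then bins the hits over two panels and prints the comparison
table in count / length / per-kb frequency form.
"""

from chromend import (
    Region,
    SimulationConfig,
    compare_regions,
    profile_features,
    scan_all,
    simulate_chromosome_end,
)

cfg = SimulationConfig(
    seed=21,
    unit_count=200,
    subtel_length=60_000,
    motif_placements=(
        ("TTAGTCCCGGTT", 5_000, "+"),
        ("SMC1B", 9_000, "-"),
        ("YY1", 12_000, "+"),
    ),
)
seq, truth = simulate_chromosome_end(cfg)
subtel = seq.residues[: truth.telomere_boundary]

hits = scan_all(subtel, seq_id=seq.id)
for mid, hs in hits.items():
    print(f"{mid:14s} {len(hs):>5} hit(s)")

tracks = {mid: [h.region for h in hs] for mid, hs in hits.items()}
panels = {
    "distal_half": Region(seq.id, 30_000, 60_000),
    "interior_half": Region(seq.id, 0, 30_000),
}
table = compare_regions(panels, tracks)
print()
print(table.to_string(index=False))

df = profile_features(tracks, Region(seq.id, 0, 60_000), bin=10_000)
busiest = df.sort_values("count", ascending=False).head(3)
print()
print("busiest bins:")
print(busiest.to_string(index=False))
print()
print("Planted motifs appear at their planted coordinates; A/T runs dominate")
print("numerically because any run longer than 5 bp qualifies in a 44%-GC")
print("background. frequency_per_kb is exactly 1000 x count / panel length.")
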