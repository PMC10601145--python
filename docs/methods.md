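# Methods

`chromend` analyses assembled chromosome ends: it delimits the terminal
telomeric repeat tract, classifies every single-base deviation from the
canonical plant telomere unit, and profiles telomere/subtelomere windows
for G-quadruplex-forming potential, GC content, CpG islands and fixed
sequence motifs. A simulator generates chromosome ends with known ground
truth so that each stage can be validated quantitatively. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic benchmarks do and do not show.

## Coordinates and alphabet

All internal coordinates are 0-based half-open on the + strand (BED
convention); report tables print 1-based inclusive positions. Residues are
normalized to `{A, C, G, T, N}`; other IUPAC ambiguity codes are mapped to
`N` with a warning rather than rejected, because public assemblies contain
them. N runs are retained in coordinates, and every scanner treats windows
with more than 10% N as unqualified and flags them, so unsequenced gaps
(such as a 50-kb gap inside an otherwise analysable arm) break features
instead of silently bridging them.

## Telomere tract detection

The plant telomere unit is TTTAGGG (G-strand); on the + strand a left-end
telomere reads CCCTAAA (C-strand). A base is *telomeric* when it lies
inside a 6-8 bp substring within edit distance 1 of the unit
("canonical-or-1-edit"): real telomeres carry single-base variants
throughout, so exact matching would truncate tracts. Insertion variants
are generated only at internal positions of the unit — a string producible
solely by appending an arbitrary base to the unit would let every tract
swallow one neighbouring non-telomeric base, making the detected boundary
systematically fuzzy.

The reported tract is the maximal terminal interval that (a) begins at the
terminus, (b) contains no run of non-telomeric bases longer than
`max_interruption` (default 21 bp, three unit lengths), (c) has purity
(telomeric-base fraction) at least `purity_min` (default 0.8), and (d)
contains at least `min_units` (default 5) recognized units. All three
thresholds are exposed because no published delimitation rule exists for
these tracts; different choices move the boundary by at most a few units.
Orientation is whichever unit yields higher purity; ties go to the
orientation conventional for the searched side (G-strand at a right/long-arm
end). Left ends are handled by reverse-complementing, scanning the right
end and reflecting coordinates, which makes the left/right symmetry exact
by construction.

Note that purity stays at 1.0 for tracts whose every unit is within one
edit of the consensus; it measures interruption content, not variant load.

## Variant decomposition (wraparound dynamic programming)

A tract is aligned against the infinitely repeated consensus with unit
costs: match 0, substitution/insertion/deletion 1. The DP column cycles
over consensus positions, so one pass minimises over every unit count
simultaneously; within-row cyclic deletion relaxation converges in two
passes because an extra full lap costs at least the unit length. With both
ends anchored at unit boundaries (the default), the total cost equals the
minimum over k of the plain edit distance between the tract and
`consensus^k` — the property the test suite checks against an independent
Wagner-Fischer brute force. A `free_start` option lets the first unit
begin mid-consensus without charge for tracts whose interior edge was cut
arbitrarily; that unit is flagged partial and excluded from event calling.

Traceback is deterministic: among co-optimal predecessors it prefers
diagonal over deletion over insertion, which (i) reports substitutions
rather than insertion+deletion pairs (those are never cheaper) and (ii)
places indels leftmost within homopolymer runs, so a deletion of one T in
TTT is always reported at the first T, and a G added to GGG is reported
before the first G. Run-internal placement is unidentifiable from the
sequence, so a deterministic canonical form is required for event-level
comparisons. Deletions at the extreme end of a tract are reported at the
offset one past the last base (there is no following base).

The inner DP loop is JIT-compiled with numba; a pure-Python fallback with
identical semantics is used if numba is unavailable. Cost grows as tract
length x unit length; a 70-kb tract decomposes in well under a second.

*Identifiability limit.* Certain cross-unit event pairs compose to a
smaller edit: a G added at the end of one unit's G-run followed by a T
deleted from the start of the next unit yields a sequence identical to a
single T-to-G substitution, and the decomposer correctly reports the
1-event description. At the default simulation rates this affects roughly
2 events per 10,000 units; it inflates substitution counts slightly and is
why event-level benchmarks compare against the realized truth with a
binomial-scale tolerance rather than demanding identity.

## Variant summaries

Percentages divide event counts by the observed tract length in bp (a
`units` denominator is available because published percentage tables do
not state theirs); the "all mutations" percentage is the exact arithmetic
sum of the three kinds. Base breakdowns report, per kind, the fraction of
events affecting each reference base (deletions, substitutions) or
observed base (additions). Multi-base indels count per base, as runs of
single-base events at consecutive offsets; an event-level aggregation can
be had by collapsing consecutive same-kind offsets. The positional
histogram bins offsets in `bin`-bp bins (default 100); the edge-enrichment
ratio divides event density in the two terminal `edge_fraction` segments
(default 10%) by the interior density, with an infinite marker when the
interior is event-free.

## G-quadruplex scanning

Scoring is run-capped: every base in a maximal G-run of length L scores
+min(L, 4), C-runs score -min(L, 4), A/T/N score 0. A sliding window
(default 25 bp, the scoring tool's customary window, exposed as a flag)
qualifies when |mean| >= threshold; the restrictive default is 1.8, with
1.2 the permissive standard. Overlapping or abutting qualifying windows of
the same sign merge into one candidate, trimmed to begin and end on the
enriched letter; mixed-sign windows never merge; candidates with more than
10% N are dropped and logged. Because hit counts depend on the merging
rule, a `merge=False` mode counts raw qualifying windows instead. The
frequency identity `frequency = 1000 x hits / scanned_length` holds
exactly for every profile, and scanning a reverse complement yields
exactly the mirrored hits with signs flipped.

A pure TTTAGGG array has window mean ~1.29 — above 1.2 (the whole G-strand
merges into one long hit) but below 1.8, where only windows enriched by
G-addition variants or distinct G4 motifs qualify. Threshold choice
therefore changes telomeric hit counts qualitatively, not just marginally.

## GC content and CpG islands

%GC is computed in 100-bp windows shifted by 1 bp, with N excluded from
numerator and denominator. The island caller follows the classic cpgplot
procedure with its published defaults: per-window %GC and observed/expected
CpG ratio `(CG count x window length) / (C count x G count)` (0 when C or
G is absent; CG dinucleotides are counted fully inside the window), a
running average over 10 consecutive windows that must reach 50% GC and 0.6
observed/expected, and maximal qualified runs of at least 200 bp reported
as islands spanning first-qualified start to last-qualified start plus one
window. Positions whose averaging span would run past the sequence end are
unqualified — no padding is invented. Reported island statistics are means
of the averaged window values over the island's qualified positions, so
they satisfy the thresholds by construction. On a flat AT background a
planted 400-bp CG-repeat block is recovered with boundary error well under
one window length; in a 44%-GC background the flanks legitimately extend
further because near-threshold background windows join the run.

## Motif scanning

Fixed motifs are matched exactly, overlapping occurrences included (this
matters for CCG-repeat arrays, where CCGCCGCCG occurrences tile every 3
bp); minus-strand hits match the reverse complement of the pattern against
the + strand and are reported in + coordinates, and reverse-complement
palindromes are reported once on +. The published analyses used a
statistical motif-search tool with stringent p-value cutoffs under which
mismatched occurrences of patterns this short are effectively excluded, so
exact matching is the default; a Hamming-distance mode (`max_mismatch`)
exists for sensitivity analysis, and the tool's E-value machinery is
deliberately not reimplemented. A/T runs (HMG-protein sites) are maximal
runs strictly longer than 5 bp, reported on + since the class is
strand-symmetric.

## Density profiles and panels

Subtelomere panels mirror the published layout: the distal 500 kb
immediately interior to the telomere boundary, an extended 5-Mb window,
and 500-kb windows whose distal edges lie 5 Mb and 50 Mb interior to the
first telomere base. Windows clipped at the sequence start are flagged;
windows falling entirely outside are omitted with a warning. Binned
profiles assign each feature to the bin containing its start, so per-bin
counts sum exactly to the total (an overlap-weighted mode exists for
visualisation); densities and panel frequencies are exact identities with
the counts and lengths.

## The simulator

The generator emulates the structure reported for plant chromosome ends: a
terminal TTTAGGG array whose units carry single-base substitutions,
insertions and deletions; deletions biased toward one T of the TTT
(producing TTAGGG), insertions biased toward extending the G-run
(producing TTTAGGGG); elevated event rates within an edge fraction at both
tract ends; and a subtelomere with GC-rich satellite blocks, CpG-island
segments, G4 inserts and fixed motifs planted at known coordinates in a
configurable-GC random background.

Defaults are the study conditions used throughout the benchmarks: per-unit
rates (p_sub, p_ins, p_del) = (0.001, 0.01, 0.02), both base biases 0.8,
edge fraction 0.1 with multiplier 3, background GC 0.44 (a typical cereal
genome neighbourhood), 1,000 units (~7 kb, inside the range implied by
published telomere lengths) and a 100-kb subtelomere as a desk-scale
stand-in for the 500-kb panel.

Design choices that keep the ground truth usable as an oracle:

- **At most one event per unit.** Multi-event units create
  alignment-equivalent alternative descriptions; at the sub-5% rates of
  interest the distortion is negligible.
- **Left-normalized truth.** Indel events are recorded at the leftmost
  position of their homopolymer run, the decomposer's canonical form,
  because run-internal placement is unidentifiable.
- **Exact bias semantics.** The unbiased remainder of insertions draws
  from A/C/T, so the configured G bias is exactly the expected G-addition
  fraction (deletions are analogous by construction: the unbiased branch
  splits over A and G by consensus composition).
- **Identifiable boundary.** The terminal 50 bp of background are redrawn
  until free of 1-edit telomere units (including junction k-mers), and
  plants may not occupy the terminal 60 bp; otherwise "the" boundary would
  be ill-defined and zero-rate recovery could not be exact.

## What the benchmarks do and do not show

The synthetic benchmarks certify algorithmic correctness: oracle
equivalence of the decomposer and G4 scanner, exact identities, boundary
and event recovery, and planted-feature recall. They do not certify
biological completeness: the background is i.i.d. rather than
repeat-structured, the telomere mutation process is memoryless across
units, no transposable-element or gene structure is simulated, and
satellite blocks are perfect tandem arrays. Consequently, passing them
shows the measurements are computed correctly, not that a particular
biological interpretation of a real assembly is unique — in real data the
tract boundary, and with it every downstream percentage, moves with the
detection thresholds, which is why those are exposed and recorded in every
run report.

## Problem sizes

Test-suite and acceptance-script runs use 10,000-unit tracts (20 seeds)
for parameter recovery, 200 random mutants up to 70 bp for decomposer
oracle equivalence, 100 random 1-kb sequences for G4 oracle equivalence,
and 50-kb subtelomeres for feature recovery — sizes at which every
statistical tolerance is set by the binomial error of the configuration
itself.
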