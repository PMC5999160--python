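# Methods

This note records the models and conventions the package implements, the
parameters that matter, what the synthetic data does and does not emulate,
and the numerical/design choices made where the design was genuinely open.

## Coordinates, alphabet, ORF definitions

All coordinates are 1-based and inclusive; an interval's length is
`end − start + 1` and its frame is `(start − 1) mod 3`. Sequences are
positive-sense RNA internally (`T` normalised to `U` on input); `N` is
tolerated but never matches a motif, never pairs in a structure, and
translates to `X`.

Two ORF definitions coexist because the frameshift-expressed ORF3 has no
initiator codon of its own:

* `AUG_to_stop` — first in-frame AUG after the previous in-frame stop,
  through the last codon before the next stop;
* `stop_bracketed` — the full codon run between consecutive in-frame
  stops.

ORF intervals exclude the stop codon. Runs truncated by a sequence end are
reported with explicit `incomplete_5prime`/`incomplete_3prime` flags rather
than dropped, because mined transcriptome contigs are routinely truncated
inside ORF2. With stops excluded on both sides, the ORF2/ORF3 "overlap
between stop codons" is the plain intersection of the two ORF intervals
(430 nt, positions 1704..2133, under the default study conditions).

Layout assignment: ORF2 is the longest AUG-defined ORF; ORF3 the longest
stop-bracketed ORF overlapping ORF2's 3′ half in the −1 frame; ORF1 the
longest AUG-defined ORF in another frame ending 5′ of ORF2's midpoint;
ORF4 the longest AUG-defined ORF starting 3′ of ORF3's end. Length ties
break toward the 5′-most start, then the lower frame index, for
determinism. Only the positive strand is searched (positive-sense virus);
small ORFs below `min_aa` (default 50) are enumerable but never assigned.
When an AUG-defined ORF has no upstream in-frame stop it is flagged
possibly 5′-incomplete; no non-AUG initiation is ever guessed.

## −1 PRF model

A signal has three parts:

1. **Slippery heptamer** `X_XXY_YYZ`, seven nucleotides whose internal
   codon boundaries must coincide with ORF2's reading frame (the first X
   is codon-final). Grammar: `YYY ∈ {AAA, UUU}`; `Z ≠ G`; `XXX` a
   homopolymer or a configured exception (default `{GGU, GAU}`, the two
   barnavirus-observed variants of the `G_RUU_UUU` consensus). The
   heptamer is always reported in this "nudged" register.
2. **Spacer** of 5–9 nt (configurable) between the heptamer's last
   nucleotide and the structure's first paired nucleotide. A bulged
   stem-loop whose raw spacer is short still validates when the distal
   helix portion (starting just past a single-nt bulge on the 5′ arm)
   falls in range — the *effective spacer*. This is handled as an explicit
   rule rather than by widening the range.
3. **Structure**: either a single-helix stem-loop (≥ `min_stem` = 4 bp,
   loop 3–12 nt, at most one single-nt bulge) or an H-type pseudoknot (two
   crossing helices, loop caps 10/15/10 nt, "compact" by construction).
   Pairing is Watson–Crick plus GU wobble (toggleable). The search is
   combinatorial — every maximal helix in a window of
   `heptamer end + max_spacer + 60 nt` — not thermodynamic; no free-energy
   model is implied, and candidates are ranked by total base pairs, then
   5′-most start. A helix whose greedy extension would pinch the hairpin
   loop below 3 nt is trimmed, not discarded.

When several heptamers qualify, all are reported and the valid signal with
the smallest (effective) spacer is marked primary.

**Fusion deduction.** Under tandem slippage the ribosome re-pairs one
nucleotide back, so one nucleotide is read twice. Convention A
(`decode_then_slip`, the default) books the `YYZ` codon to the zero frame
and resumes −1 decoding at the `Z` nucleotide; convention B shifts after
`XXY`. The two conventions change the junction residue but provably not
the total: the zero-frame part loses exactly the codon the −1 part gains.
A stop codon in the fused frame before ORF3's stop is an error naming the
position, not a silent truncation.

## TM prediction

A documented stand-in for web-tool TM predictors: Kyte–Doolittle hydropathy
averaged over a centred window (default 19 aa, truncated at the termini),
thresholded at 1.6, with maximal runs of at least 10 positions reported as
segments. Exact segment counts from other predictors are not reproduced and
are treated as non-binding diagnostics; the pipeline relies only on the
coarse signature "≥ 2 segments N-terminal to the protease-region boundary
in P2, none in P1", which is robust to the predictor choice. The
protease-region boundary (aa 290 by default) comes from homology evidence
outside this package's scope and must be supplied, never computed.

## Misassembly detection

`score_architecture` counts seven binary features: ORF1 present with its
start 5′ of ORF2's; ORF1 in the −1 frame relative to ORF2; ORF3
overlapping ORF2 in the −1 frame; a valid PRF signal in that overlap; ORF4
present 3′ of and not overlapping ORF3; a TM cluster (≥ 2 segments) before
the P2 boundary; ORF1 present with zero TM segments in P1. An intact
default genome scores 7; a 1-nt indel in the ORF1/ORF2 overlap typically
scores 4–5; random 4.2-kb sequences average ≈ 2 and never exceeded 5 in
the frozen empirical null.

`scan_indels` is exhaustive: every position in the region × (deletion +
four insertions), each variant re-annotated and re-scored identically;
hypotheses achieving the maximum score are returned only when they improve
on the input genome's score. Results are grouped into
**positional-ambiguity windows**: placements whose after_positions are
separated by less than one codon belong to one window, reported by its
5′-most `after_position` and extent. Homopolymer runs are the canonical
case (indels inside a run give byte-identical variants); the window is
wider wherever the local register shift leaves both affected frames sense
— inside a hydrophobic block, for instance — and an isolated interior
position where every inserted base creates a stop does not end a window.
The architecture score localises; it cannot pick a residue inside the
window. `read_support`/`resolve_with_reads` do that by exact matching of
the corrected local sequence (± `flank`, default 15 nt) against reads in
both orientations, mirroring how archived reads settle the identity of a
corrected residue in practice. When no reads are given, insertion groups
whose members differ only in base are reported with base `N`.

Deletion convention: `(kind="deletion", after_position=p)` removes the base
at `p + 1`, so an insertion and a deletion at the same `after_position` are
exact inverses.

## Read walking

Reads (either orientation) are recruited to a terminus via exact 21-mer
anchors, verified over their whole overlap with ≤ 2 mismatches, and must
agree exactly with the last 10 consensus columns (chimera guard). Columns
are appended by majority vote, ties broken A<C<G<U, and the *winning base*
must carry ≥ `min_support` reads (default 2) — requiring only the total
vote count proved fragile: a 1–1 split at a thinly covered column would be
settled alphabetically and the wrong base then freezes recruitment. The 5′
walk is the 3′ walk on the reverse complement, which is exact because the
k-mer index holds both read orientations. Extension near a true genome
terminus necessarily stalls a few nucleotides short: terminal coverage
decays below the support threshold (at depth 20 and 100-nt reads, the last
~5–15 nt). Qualities, when present, are carried but ignored by the
consensus.

## Synthetic data: what it emulates, and what it does not

The generator plants, on a 4206-nt genome by default: ORF1 (170 aa) nested
in the −1 frame inside ORF2's 5′ region with a bracketing stop before its
AUG; ORF2 (700 aa) with an in-frame stop exactly 3 codons upstream of its
AUG; a stop-bracketed ORF3 overlapping ORF2 by 430 nt in the −1 frame; a
slippery heptamer (`G_AUU_UUU` by default, `G_GUU_UUU` selectable) with a
planted compact pseudoknot — or a hairpin, or a bulged hairpin with raw
spacer 3 / effective spacer 7 — and a P2+3 fusion of 1076 aa by
construction; ORF4 (180 aa) downstream and non-overlapping; five 21-aa
hydrophobic blocks in P2's N-terminal region and none in P1; optional
decoy heptamers followed by a pairing-free A/C window; optional lesions
(one indel, terminal truncations of e.g. 879 and 31 nt). Reads are
uniform-start, Poisson-count, substitution-error-only, strand-random.

Construction is codon-wise, with three filler regimes inside ORF2:

* across ORF1's span, an alternation of `AUA`/`CAA`/`CGA`/`ACA` with
  `AAC`/`ACC`/`GAC`/`GGC` — chosen so ORF1's frame is deterministically
  stop- and AUG-free, no hydropathy window can cross the TM threshold, the
  +1-shifted register (where a deletion pushes the ORF2 reader) carries
  frequent stops, and no single-base edit of any codon pair can create an
  AUG that reads into an intact planted frame. These properties are what
  make single-indel corrections localisable at all;
* across the ORF2/ORF3 overlap, random C/G-ending sense codons: the −1
  frame then cannot read a stop, and no slippery heptamer can arise by
  chance (YYY needs an A/U at a codon-final position);
* elsewhere, random sense codons (hydrophilic-only until past the TM
  boundary region, so chance filler cannot add a sixth TM segment).

TM blocks draw from C-ending V/L/I/F codons with two fixed polar (S/T)
positions per block — enough sequence diversity that reads cannot anchor at
the wrong phase of a block, never enough to clip the block's hydropathy
run. A final validation pass re-checks every constraint with independent
string scans (planted anchors, sense frames, competing-ORF scans in all
frames, slippery uniqueness) and redraws the filler from the same seeded
stream on failure, so generation is deterministic per seed.

What the generator does **not** emulate: codon-usage or composition realism
(the filler alphabets are constraint-driven), indel sequencing errors,
quality-score structure, secondary structure outside the planted signal,
and repetitive or paralogous sequence beyond what the filler regimes
produce. Passing tests therefore demonstrate the correctness of the
inference chain under controlled conditions, not performance on arbitrary
field data — in particular, the read walker's behaviour in genuinely
repetitive genomes and the indel detector's behaviour under multiple
simultaneous errors are out of scope by design.

## Problem sizes and determinism

The acceptance computations use the default study conditions throughout:
200 seeded replicates for planted-signal recovery, 100 single-indel
genomes for misassembly parameter recovery (one uniform-random deletion in
the ORF1/ORF2 overlap, full-overlap scan), and 20 truncated-genome
replicates (879 + 31 nt, depth 20, 1 % error) for the walker. Every source
of randomness descends from one integer seed; reports are JSON with sorted
keys, logs carry no timestamps or absolute paths, and identical
(inputs, config, seed) reproduce every output byte-for-byte.

## Known limitations

* The structure finder maximises base pairs, not free energy; it can
  prefer a geometrically larger alternative over the "intended" fold, and
  reported stem coordinates for planted hairpins may differ by a base pair
  where a neighbouring nucleotide happens to pair. Signal validity and
  heptamer position are unaffected.
* The architecture score is a 7-level integer; its ambiguity windows can
  span tens of nucleotides inside low-complexity or hydrophobic stretches.
  That is a property of the evidence, not the search — reads are the
  instrument for sub-window resolution.
* `upstream_inframe_stop` reports distances only within the available
  sequence; a 5′-truncated contig yields `None` ("possibly 5′
  incomplete"), never an inferred position.
* Accession-based workflows (annotating real GenBank records, walking real
  SRA read sets) use exactly the same code paths but are not exercised by
  the test suite, which is download-free by design.
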