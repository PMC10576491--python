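# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinates, strands and vocabulary

All genome coordinates are 1-based inclusive (GenBank convention);
conversion to Python indices happens only inside `mito_io`. A feature with
`start > end` wraps the origin of a circular record. Strands are labeled
J (majority coding strand, the one stored in the record sequence) and
N (minority strand; N-strand genes are read on the reverse complement).
J/N map to GenBank +/− on write; the J/N vocabulary is kept in reports
because it is how mitogenome papers print strand assignments.

Gene names use a controlled vocabulary (nad1–6, nad4L, cox1–3, atp6, atp8,
cytb, 22 tRNA symbols with isoacceptor tags for trnL/trnS, rrnS, rrnL,
CR/CR1/CR2). A packaged synonym table maps common qualifier spellings
(ND2, COI, CYTB, 12S, D-loop, tRNA-Phe, …); ambiguous tRNA-Leu/Ser names
are resolved from a UUR/CUN/UCN/AGY tag anywhere in the qualifiers.
Unmappable features become warnings, never silent drops or crashes.
When a file contains two control regions annotated generically, CR1/CR2
labels are assigned by circular order from the trnF anchor, which makes
them independent of where the flat file happens to start.

## Gene order and TDRL search

A `GeneArrangement` is an ordered, stranded circular gene list; two
arrangements are equal when a rotation makes them elementwise equal, and
the trnF anchor (adjacent to rrnS in both the typical and the rearranged
avian order) fixes a canonical rotation for reports. Breakpoints between
two orders are directed adjacencies on the J-strand reading order present
in one and absent in the other, with CR1/CR2 canonicalized to CR so that
single- and double-CR orders are comparable.

The TDRL search enumerates every contiguous block up to 8 genes
(exhaustive at this size: ~20k replays for a 38-gene circle) and every
survivor pattern — first or second copy per duplicated gene, plus "both"
for genes explicitly allowed to retain two copies (the control region,
whose second copy is the remnant CR2 downstream of trnE). A candidate is a
solution when replaying duplication-then-loss on the ancestral order
reproduces the observed order up to rotation; no-op patterns are excluded,
so identical inputs certify "no event needed" with an empty list. TDRL
preserves gene orientation by construction; inversions are out of scope.
An empty result is meaningful: the enumeration is exhaustive, so it
certifies that no single orientation-preserving TDRL of that block size
explains the rearrangement.

## Composition and skews

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C). Ambiguity codes (including
N) are counted under `other` and excluded from percentage denominators and
from both skew numerators and denominators; a zero denominator yields a
null skew rather than a value. Percentages are over unambiguous bases.
The PCG concatenate excludes termination codons and uses coding-sense
strands (N-strand genes reverse-complemented), because codon-position
statistics require reading frame; whether genome-wide percentages should
include ambiguity codes is a reporting convention, and the one used here
(exclude) is documented rather than asserted to match any external tool.
Internal values are full precision; serialization rounds percentages to 2
decimals, skews to 4, copy numbers to 1.

## Codon usage

The vertebrate mitochondrial code (NCBI table 2) is used throughout: ATA
is Met, TGA is Trp, and AGA/AGG act as terminators (they are reported in
the stop inventory but never translated). Consequently Met and Trp are
two-codon families and there are no single-codon families. A CDS whose
length is 1–2 nt short of a whole codon ends in an incomplete stop (T or
TA) completed to TAA by polyadenylation; assembly pads it and flags
`padded`, while the inventory reports the stop verbatim as annotated.
Start/stop codons are reported exactly as read — including unusual
terminators such as GAA — so discrepancies between records remain visible
instead of being normalized away.

RSCU is computed per amino-acid family: RSCU(i) = X_i · n / X for family
size n and family total X, over the concatenated PCGs of a record (the
final, possibly padded, codon of each CDS is dropped first). Family sums
equal n whenever X > 0, which the tests verify against an independent
brute-force 3-mer counter. The L1/L2/S1/S2 labels follow the common
reporting convention L1 = UUR-Leu, L2 = CUN-Leu, S1 = AGY-Ser,
S2 = UCN-Ser; the labels only subdivide reports, not the RSCU families.

## Control region

Domain boundaries are inputs; the packaged default (I: 1–424, II: 425–859,
III: 860–1104) is the published partition of the *P. fuscatus* CR1 and is
applied automatically only when the CR is at least 1,104 nt. Boundaries
for other species must be supplied explicitly — proportional rescaling is
deliberately not attempted.

Conserved boxes are matched by Hamming distance over fixed-length windows
(no indels; boxes are short and indel handling would add complexity
without improving the reported statistics). Default mismatch cap 3; the
best window is reported, leftmost on ties; boxes with no window within the
cap are reported absent. The shipped library contains the study boxes
(C-string, F, E, D, C, bird-similarity, B, CSB1; the E and C patterns had
a spurious whitespace in the source text, stored with the space removed)
plus approximate literature-consensus patterns for CSB2/CSB3/OH/LSP/HSP
flagged `provenance: literature_consensus` — these exist so their absence
is reportable, and no quantitative claim rests on them.

C-strings are maximal cytosine runs allowing a bounded number of single
non-C interruptions, each flanked by C on both sides; among overlapping
candidate windows the longest (leftmost on ties) non-overlapping windows
are reported.

The tandem-repeat detector seeds candidate periods from recurrence
distances of exact 8-mers, extends each seed with X-drop local alignment
of the sequence against itself at that lag (match +1, mismatch −2, stop 6
below the running best), and keeps regions with at least `min_copies`
(default 1.8) copies and `min_identity` (default 80%) aligned identity.
Regions are ranked by score (aligned matching positions, so longer and
cleaner repeats win), overlapping lower-scoring regions are suppressed,
and each region reports period, copy number = region length / period, and
a columnwise majority consensus (ties resolved toward the first unit).
This is deliberately simpler than the wraparound dynamic programming of
the dedicated repeat-finder tools and targets the near-exact short-period
repeats of mitochondrial control regions; chance flank matches can stretch
a reported region by a few bases per side (bounded by the X-drop), which
shifts the fractional copy number by at most a few hundredths to tenths
but never the period. Indels inside repeats are not modeled.

## tRNA structure

Structure specs (arm intervals, anticodon position) are inputs, not
predictions; folding is out of scope. Sequences are handled as DNA.
Stems pair antiparallel; a pair's class depends only on the unordered base
pair: {A,T} and {G,C} are Watson–Crick, {G,T} is the wobble pair, all else
mismatch. Conservation of an arm across species is the strict criterion —
percent of stem columns identical in all species on pre-aligned input;
majority-based alternatives are not implemented.

## Distances and neighbor joining

p-distance = mismatches / compared sites. Sites with gaps, N or any
ambiguity are missing: complete deletion (default, matching the common
tool default) drops the column for all pairs; pairwise deletion excludes
per pair. The two modes agree exactly on gap-free data, and no ordering
between them is asserted in general. The p-distance may violate the
triangle inequality; nothing here assumes otherwise.

Neighbor joining is the classic agglomeration with two determinism rules:
Q-criterion ties break toward the lexicographically smallest pair of node
labels, and a negative branch length is clamped to zero with the deficit
moved to the sister edge, preserving the pair's summed length. Trees are
written unrooted with a trifurcating root and 6-decimal branch lengths.
On tree-additive matrices NJ provably recovers the generating topology,
which the tests check on random 5–8 taxon trees and against an independent
NJ implementation.

## Synthetic data

The generator lays out the chosen template order with realistic lengths:
PCGs at typical avian sizes (e.g. cox1 516 codons, atp8 55), tRNAs 66–72
nt on the generic cloverleaf layouts, rRNAs 975/1,600 nt, CR1 1,104 nt,
remnant CR2 240 nt, spacers of 0–1 nt, and a tail fill to the configured
genome length (default 16,950 bp, inside the observed 16.9–17.0 kb band).
Defaults are the study conditions: base-frequency targets A 29.43%,
C 32.75%, G 14.68%, T 23.10% (normalized), all-ATG starts, terminators
TAA/TAG with AGG for cox1 and cox3, AGA for nad5, incomplete TA for nad2
and T for nad4, a codon bias favouring CTA/CGA/TCC/GCC, the printed 46-bp
repeat unit at 2.0 copies in CR2, the 18-nt C-string and the full box set
in CR1, and seven planted stem irregularities (four G-U wobbles plus the
A-C/C-C/U-C mismatches reported for trnF/trnV/trnG).

What passing plant/recover tests show — and what they do not: the genome
is structurally faithful (complement, order, strands, frames, planted
signals recoverable), but coding regions are random codons, not homologs;
gene overlaps, indels, heteroplasmy and length variants are not simulated;
and the fixed ATG/terminator and stem constraints shift whole-genome
composition a couple of percentage points from the random-fill targets
(the C>A>T>G ordering is preserved; recovery is asserted within ±3 points,
while pure random fills at n = 17,000 recover targets within ±0.8).

The alignment simulator applies an independent per-site substitution with
constant probability q on every branch (a substituted site picks one of
the other three bases uniformly), so the expected p-distance across k
branches is 3/4 · (1 − (1 − 4q/3)^k) and simulations can be checked in
closed form. Branch lengths in the input Newick are ignored by design —
the simulator tests distance/tree code, not evolutionary realism; there is
no rate heterogeneity and no indel process. Simulation-based checks in the
tests use 2,000–10,000 sites, sizes at which the closed-form and topology
checks are already decisive.

## Report pipeline

The reporter only assembles module outputs; nothing is recomputed.
Cross-record averages are unweighted arithmetic means of per-record
percentages. JSON is written with sorted keys so a rerun on identical
inputs is byte-identical. Reports are validated against a shipped minimal
JSON schema by a small in-package structural validator (required keys and
types); per-record stage failures are isolated into a warnings list so one
malformed record cannot abort a batch.

## Known limitations

- Annotation is consumed, never produced: no tRNA scanning, no assembly.
- The TDRL model covers single events without strand inversion; multi-event
  distances and inversion models are out of scope.
- Box scanning has no indel tolerance; a box disrupted by an insertion
  would be reported with inflated mismatches or as absent.
- The repeat detector's boundary placement can differ from wraparound-DP
  tools by a few bases on low-complexity flanks (period is unaffected).
- Published inter-species distance values depend on the exact alignments
  and deletion mode used by their authors; reproducing them requires those
  alignments as input.
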