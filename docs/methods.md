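# Methods

This note documents the models, rules and numerical choices behind
`prokannot`, what the synthetic fixtures do and do not emulate, and the
design decisions taken where the problem was genuinely open.

## Coordinates and formats

All public coordinates are 1-based inclusive, matching GenBank, GFF3, AGP
and the NCBI feature table; conversions to Biopython's 0-based half-open
locations happen only inside the readers/writers. Compound (join)
locations are read as their outer span with the original location string
preserved in a qualifier and are never written back as joins — microbial
CDS are contiguous. Translation uses NCBI genetic code table 11
throughout; alternative start codons (GTG, TTG, …) translate as Met at
position 1 of a complete CDS. Unknown feature keys pass through verbatim
so files annotated with viewer-specific keys survive round trips.

GenBank records are written with a fixed date line so that repeated runs
of the same inputs are byte-identical — determinism is treated as a
contract, not a convenience.

## The non-bleeding spacer

Contigs are concatenated with
`5'-NNNNNNNNNNTTAGTTAGTTAG NNNNNNNNNN-3'` (32 nt, written here with a
cosmetic space). The 12-nt core TTAGTTAGTTAG contains an in-frame stop in
all three forward frames and, as its reverse complement CTAACTAACTAA, in
all three reverse frames. `verify_spacer_stops` proves this property for
any candidate spacer by embedding it between stop-free poly-A flanks and
scanning all six frames; codons containing ambiguity codes count as stops
only when *every* resolution is a stop, so N-rich spacers cannot pass on
a technicality. Custom spacers are validated (must score 6/6) before use.

N-runs ≥ 12 nt inside a contig are patched by centering the 12-nt core in
the run. This preserves sequence length — keeping all downstream
coordinates stable — and deliberately does not split the contig; the goal
is only that no predicted gene spans the undefined region.

## Gene models

The built-in caller reports, per frame and strand, the longest ORF of
each maximal stop-to-stop segment: first start codon (default
{ATG, GTG, TTG}) to terminating stop, minimum 90 nt. Codons containing N
are neither starts nor stops. This is a deliberately simple stand-in for
external gene callers (Glimmer, Prodigal, …), which plug in through the
same gene-model interface; its value is that it is exactly specifiable
and therefore testable against brute-force enumeration.

**Additive merging.** Calls from multiple models are grouped by
(strand, stop coordinate) — alternative starts of the same gene — and the
longest call per group is kept; groups with distinct stops are all
retained even when they overlap. Grouping by shared stop (rather than by
overlap) is an interpretive choice: the stop codon is the stable anchor of
a prokaryotic gene, while start-codon choice is what callers disagree on.
The operation is commutative, associative and idempotent, and every input
stop survives, so merging is order-independent and maximally inclusive.
Identical spans from different callers deduplicate, with their caller tags
merged. Consolidation sorts by leftmost coordinate and assigns gene
numbers 1..N with no gaps; it is a fixed point under reapplication.

## Intergenic ORF rescue

Intergenic regions are the complement of the gene spans, each extended
`reach_nt` (default 30 nt) into the flanking genes. Flattened mode uses
all genes regardless of orientation; oriented mode computes regions per
strand against same-strand genes only, treating each strand independently
(an opposite-strand gene does not block an antisense region). igORF
candidates use the caller's ORF definition with a lower floor (default
60 nt); stop-less open-ended candidates are admitted only where a region
abuts a contig boundary, and are flagged partial. Acceptance requires a
homology hit strictly below the e-value threshold (default 1e-10), so a
threshold of zero accepts nothing. Rescued candidates re-enter the model
through the ordinary merge + consolidate path. The two halves of a
frameshifted gene are reported as two calls; joining them into a single
pseudogene feature is out of scope.

## Homology searches and statistics

All pipeline logic consumes typed hit rows (the 12 standard tabular
columns plus optional subject length and description), so any engine that
emits that dialect plugs in: adapters shell out to BLAST+ binaries, and a
built-in searcher keeps the test suite and fixtures fully offline and
deterministic.

The built-in searcher is an ungapped seed-and-extend protein aligner:
identical 3-mer seeds, BLOSUM62 extension with an X-drop of 20, one best
HSP per query/subject pair. Bit scores use the ungapped Karlin–Altschul
parameters for BLOSUM62 (λ = 0.267, K = 0.041):
`bits = (λ·S − ln K)/ln 2`, `E = m·n·2^(−bits)` with m the query length
and n the total database residues. It is not a BLAST replacement — no
gaps, no composition adjustment — but self-hits and near-identities, which
is what rescue and transfer rely on, are found with near-certainty, and
its determinism makes call-count and reuse oracles exact.

Best-hit selection minimizes (e-value, −bit score, subject id); the
lexicographic final key makes tie-breaking stable under permutation. The
keyword filter removes hits whose description contains any stop keyword as
a case-insensitive substring.

**rRNA extrapolation.** A partial alignment of the genome against a
full-length reference rRNA is extended to the full subject: on the plus
strand, predicted start = qstart − (sstart − 1) and predicted end =
qend + (subject_len − send); minus-strand alignments mirror the
computation. Predictions are clamped to the sequence with partial flags.
The reference length is taken from the hit row (column 13) rather than
from a bundled reference database.

## The annotation rule engine

Products follow three literal rules: no hits → `unknown`; hits only above
the threshold → `conserved hypothetical`; otherwise the best hit's
description, sanitized by stripping a leading subject-id token,
database tags (`sp|...|...`-style) and a trailing `[organism]` bracket.
A TIGRfam profile hit below its threshold overrides gene name and product
for both the gene and CDS features; its curated gene designation is used
when the preference flag is set, and E.C. numbers parsed from the profile
row are added to the CDS. Profile databases are searched in selection
order and the cascade stops, per gene, at the first database with a
below-threshold hit; when none qualifies, all databases' results are
retained.

Analysis features are emitted by default as `misc_feature` with a note
naming the analysis (standard parsers reject custom keys); a strict mode
preserves the original keys with a constant colour qualifier per key for
viewers that use them. Updating an existing annotated record replaces
only the selected analysis keys and can preserve existing gene/CDS
qualifiers verbatim to protect manual curation.

The result store writes one tabular file per gene per analysis, headed by
the gene number. The reuse integrity check is: the file parses and its
header names the expected gene number; anything else is regenerated for
that gene only.

## Annotation transfer

Three passes over the old gene set, each consuming what the previous one
left: (1) genes whose CDS nucleotide sequence occurs exactly once among
the new model's genes transfer directly — a non-unique exact match falls
through so duplications surface as ambiguous rather than being guessed;
(2) anchored protein containment classifies extensions and truncations,
anchoring at the C-terminus (with the initiator Met ignored) because start
codons vary far more than stops between assemblies; (3) the remainder is
aligned against still-unclaimed new genes and transfers at ≥ 80% protein
identity (default) over the aligned span. Already-claimed new genes are
excluded from pass 3 candidates. More than one equally best candidate →
AMBIGUOUS; none → NO_MATCH; both logged. The outcome classes partition
the old gene set, and lowering the identity threshold can only increase
the number of transfers.

## Submission files

Feature tables follow the NCBI 5-column format: coordinates are listed
5'→3' (swapped for minus-strand features), `<`/`>` prefixes mark partial
ends, qualifiers are emitted on indented lines, and an optional whitelist
restricts which qualifiers appear. Internal bookkeeping qualifiers
(colour, gene number) are never emitted. AGP output is v2.0 with one W
line per contig and N gap lines of the spacer length between them,
`gap_type contig, linkage no, evidence na` — the spacer represents an
unordered assembly join. Locus tags are prefix + zero-padded 4-digit
counter in coordinate order (widened to 5 digits with a warning past
9999); a gene/CDS pair at one location shares one tag, and multi-replicon
submissions can number continuously across records or restart per record.

## Metagenome profiling

Exactly identical reads (case-insensitive) collapse to the first-seen
representative carrying the group's frequency. Each representative is
searched — by default through all six reading-frame translations against a
protein database — and only its single best hit is considered: the
module's purpose is a frequency-by-similarity overview, not
multi-assignment. Hits below the e-value ceiling contribute the read's
frequency to the subject's count in the stringent bin `[0, split)` or the
relaxed bin `[split, ceiling)`; the split defaults to 1e-50. Collapsing
then profiling is exactly equivalent to profiling duplicates one at a
time, and bin totals are invariant to read order. Length filtering is
exposed as flags because e-values are not comparable across very
different read lengths.

## Synthetic fixtures

The generators are pure functions of (parameters, seed); each draws from
its own named stream of a seeded PRNG, so adding a generator never
perturbs existing fixtures.

Genomes are built from a stop-dense background (random 18-mers
interleaved with the 12-nt all-frame stop core, so no background ORF can
reach the caller's 90-nt floor) with planted genes — start codon, sampled
sense codons, stop codon — each preceded by an in-frame stop so the
caller's first-start rule recovers the planted span exactly. Chance ORFs
in the other five frames of a gene's interior are then repaired by
planting stop codons in the offending frame, under the constraints that
no planted gene's start, body or stop is broken; repairs avoid
overwriting earlier repairs so overlapping ORFs in different frames
cannot undo each other. The default study genome is 12 kb with ten 300-nt
genes on alternating strands — small enough that the full suite runs in
seconds, large enough that every stage (concatenation, calling, rescue,
transfer, profiling) operates at realistic per-gene scale.

Assembly perturbations edit selected genes: 5' extension/truncation by
whole codons (yielding anchored-containment truth), forced
non-synonymous substitutions at a 1% nucleotide rate (yielding
pass-3 truth with computable identity), and cassette duplication
(yielding ambiguity truth). The frameshift fixture engineers the codons
at the deletion site (…CTA|ATG…) so that deleting one base creates an
immediate in-frame stop and leaves an in-frame start for the downstream
half — both halves are then recoverable ORFs with deterministic stop
coordinates. Read sets reverse-translate random windows of database
proteins with random codon choice and strand, plus background reads and
exact duplicates at a set rate, with a per-read source truth table.

What the fixtures do **not** emulate: real codon usage and GC skew,
ribosome-binding signals, overlapping genes, sequencing error models
beyond uniform substitution, and real database redundancy. Passing tests
therefore demonstrate that the algorithms implement their contracts
exactly — not that the built-in caller or searcher rivals Prodigal or
BLAST on real data; those tools plug in through the engine and gene-model
interfaces for production use.

## Problem sizes and tolerances

The acceptance script and test suite run at: 100 random concatenations
(1–50 contigs), 50 random 5-kb sequences for the caller oracle, 50
rotation fixtures, a 10-gene genome for rescue/transfer/profiling, and
80 reads at 25% duplication. All checks are exact (set equality, integer
conservation, truth-table identity); the only real-valued comparisons are
percent-identity thresholds, which use the documented defaults (80% for
transfer pass 3) rather than tuned values.

## Known limitations

- The built-in searcher is ungapped; a single indel splits an alignment
  and can understate identity. Transfer pass 3 is therefore conservative
  in the presence of indels (real engines can be plugged in).
- Rotation refuses linear molecules unless forced, and the choice of the
  new origin (e.g. locating *dnaA*) is the user's.
- Frameshift halves are rescued as two independent igORFs; no joined
  pseudogene feature is emitted.
- Promoter prediction and RBS detection are out of scope.
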