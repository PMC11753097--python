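# Methods

This note documents the models, conventions and numerical choices behind
`mavekit`, and what its synthetic-data tests do and do not demonstrate
about real data.

## The variant grammar

`mavekit` parses a deliberately strict subset of HGVS sequence-variant
nomenclature suited to multiplexed-assay targets, which usually lack
database reference sequences.  Supported: substitution, deletion,
duplication, insertion, deletion-insertion and the target-identical
variant (`=`) under the `g.`/`c.`/`n.` (nucleotide) and `p.` (protein)
prefixes, including bracketed multi-event variants.  Excluded, with a
dedicated `UnsupportedFeature` error: uncertainty notation (`?`,
parenthesised predictions), frameshift shorthand, repeats, multi-molecule
alleles, mosaicism/chimerism, and the legacy Enrich2 tokens `_wt`/`_sy`.
The rationale for strictness is validatability: every accepted string can
be checked residue-by-residue against a local target sequence.

Conventions that pin down a unique canonical form:

- Coordinates are 1-based, fully closed; no leading zeros; ranges require
  `start < end`; single positions are never written as degenerate ranges.
- Nucleotides are uppercase `ACGT` only; prefixes lowercase only.
- Amino acids use three-letter codes (`Ter` for stop).  One-letter input
  is rejected rather than auto-converted — silent conversion would make
  round-trips ambiguous.
- Multi-event variants must be written in ascending position order with
  non-overlapping covered positions; two events with the same start are
  rejected outright, since no supported pair of kinds can co-occur at one
  position without overlap.  The parser never re-sorts.
- Offset (intronic) positions such as `122-6` are accepted only in splice
  context (the `hgvs_splice` column).  They cannot be checked against a
  contiguous target, so elsewhere they raise `OffsetNotAllowed` and in
  splice context they receive format-only validation (an info-level
  `FORMAT_ONLY` finding).

The canonical form is exactly the accepted language:
`format_variant(parse_variant(s)) == s` for every accepted `s`, and the
formatter refuses variants violating the invariants.  One representation
detail: protein insertions (`p.Cys3_Glu4insTrp`) state their flanking
residues, which are stored in the event's `ref` field (two three-letter
tokens) so they can be checked against the target; nucleotide insertions
state no reference residues and keep `ref` empty.

Out of scope by design: projecting nucleotide variants onto protein
consequences, 3'-shifting/normalisation of indels, and cross-transcript
normalisation.  Rows may populate `hgvs_nt` and `hgvs_pro`
simultaneously, but their mutual consistency is not checked.

## Target consistency

A variant is consistent with a target when every position it touches is
within bounds and every reference residue it states matches the target.
Protein variants validate against a protein target directly, or against a
coding nucleotide target via standard codon table (NCBI table 1)
translation; internal stop codons translate to `*` and add a warning
finding.  No alternative codon tables and no reverse-complement handling:
score sets define their own target on its own strand.

Accession-anchored variants (the saturation-genome-editing case) validate
through a `SequenceLookup` protocol — any deterministic callable mapping
(accession, 1-based closed interval) to residues or `None`.  Shipped
implementations are an in-memory map and a local FASTA file; an
unresolvable accession or interval yields an `UNRESOLVED_ACCESSION` error
finding rather than an exception, leaving it to the caller whether a
local copy of the subsequence exists.  When a lookup simply returns the
local target, accession mode and direct mode produce identical findings.

Validators collect findings (code, severity, message, locus/row/column)
instead of raising: a table with many problems yields one report listing
them all.  `valid` is true exactly when no error-severity finding exists.

## Tables

Score tables are RFC 4180 CSVs with a mandatory header; reserved columns
are `hgvs_nt`, `hgvs_splice`, `hgvs_pro` and `score`; any further columns
must be numeric-or-missing.  Exactly two tokens denote missing values:
the empty string and `NA`.  Cells are held as strings internally so a
read/write cycle preserves bytes; numeric views are computed on demand.

A row's identity is its tuple over the reserved variant columns;
duplicate tuples are errors (one finding per extra occurrence).  A row
may miss its score — variants can legitimately carry counts but no score
after filtering — but an entirely missing score column is an error, and
in count-consistency validation a row with neither score nor any count is
flagged (`MISSING_DATA`).  Count tables must cover exactly the score
table's variant tuples (symmetric `UNMATCHED_VARIANT` findings
otherwise), with nonnegative counts.

## Records, accessions and meta-analyses

Accessions follow `urn:mavedb:NNNNNNNN[-x[-k[#v]]]`: 8-digit zero-padded
experiment-set number, lowercase-letter experiment suffix, positive
score-set index, and variant index after `#`.  A `tmp:` namespace marks
unpublished records.  Hierarchy validation checks that every child's
accession extends its stated parent's, that parents exist, that at most
one reference per record is primary, and that meta-analysis source edges
resolve and form a DAG (cycle detection via networkx).

Meta-analysis score sets represent transformed or combined scores —
imputation, cross-assay combination — linked to their sources by
accession.  They never modify their sources; the generator and tests
verify source tables are byte-identical before and after attachment.
Because every score set needs a parent experiment, the generator places
the meta-analysis score set under its own experiment within the same
experiment set; meta-analyses spanning experiment sets are permitted and
surfaced as an info-level finding.  The advisory one-experiment-per-assay
convention is likewise info-level, never an error.

## Archives

A bulk release is one `metadata.json` (all structured record metadata,
sorted by accession, sorted keys, 2-space indent, trailing newline) plus
`tables/` holding one scores CSV per score set and a counts CSV where
counts exist; filenames are accessions with `:` replaced by `-`.  The
JSON layout is defined by the schema shipped at
`src/mavekit/schemas/archive.schema.json`; `format_version` guards future
changes and `version_tag` labels the snapshot so a specific release can
be cited.  Numbers serialize as shortest round-trip decimals and missing
values as empty cells, which together with pinned line endings makes
double-writes bit-identical.  Reading tolerates missing or unreadable
table files (error findings, not crashes); only an absent or unparseable
`metadata.json` raises `CorruptArchive`.  An optional variant-accession
column in CSVs is deliberately not emitted.

## Summaries

The histogram uses the Freedman–Diaconis rule (bin width
2·IQR·n^(−1/3)), which is robust for the bimodal distributions typical of
MAVE scores; when the IQR is zero it falls back to 30 equal-width bins,
and a degenerate min==max range is widened by ±0.5.  Counts plus the
missing tally always equal the table's row count.

The effect matrix has a fixed row alphabet: at the protein level the 21
three-letter codes (20 amino acids + `Ter`) sorted alphabetically plus a
final `del` row (22 rows); at the nucleotide level `A,C,G,T,del` (5
rows).  Non-coding targets are summarised at the nucleotide level.  Only
single-event substitutions and single-position deletions have a natural
cell; insertions, duplications, delins, multi-position deletions and
multi-event variants are tallied in `n_excluded_multi` but still
contribute to the histogram.  The conservation law `filled cells +
excluded + single-site rows lacking a score == row count` is asserted
over generated score sets.  `wt_mask` records the target residue's row
per column; on a validated table no substitution can populate it (a
substitution's alternate residue cannot equal the matching reference).
Whether to colour wild-type cells is left to the renderer.

## Synthetic data

The generator defines the conditions every property is tested under.
Defaults: a 90-nt coding target (built from the 61 non-stop codons, so
translations have no internal stops), 200 variants, 10% bracketed
double-substitutions, 10% single-position deletions among the singles,
and scores from a two-component Gaussian mixture — mean 0 (sd 0.2, weight
0.35) for the loss-of-function class and mean 1 (sd 0.15, weight 0.65)
for the wild-type-like class, the common normalisation for growth-based
selections — with 5% of scores missing.  Counts are uniform integers in
[50, 2000) per variant for pre/post-selection columns; no attempt is made
to model sequencing noise or make counts statistically consistent with
scores.

All randomness flows through numpy's PCG64 generator, seeded from the
spec with a separate stream per purpose (target, variants, scores,
defects), so identical specs are bit-reproducible across platforms and
adding defects never perturbs clean rows.  Defect seeding consumes
distinct clean single-substitution rows so the error count downstream is
exactly the defect count: a corrupted reference residue is guaranteed to
differ from both the true residue and the alternate (one `REF_MISMATCH`,
no accidental duplicate), variant-string corruptions are applied to the
score and count tables in lockstep (no spurious `UNMATCHED_VARIANT`),
and duplicated rows are copied verbatim from untouched rows.

What passing these tests shows: the validators are sound and complete
against the defect classes the generator can express, and the formats
round-trip losslessly.  What they do not show: behaviour on the
messiness of real submissions — inconsistent transcript annotations,
locale-formatted numbers, mixed variant columns with conflicting
coordinates, or score distributions far from a two-component mixture.

## Problem sizes

The shipped test suite and acceptance script run the properties at the
sizes the package's guarantees are stated at: 10,000 round-trip strings
with 2,000 single-character fuzz mutants, 200 defect-seeded score sets of
40 variants, 1,000 target-consistency draws on an 80-nt target, 50
archive round-trips of 10-variant collections, and 20 summary
conservation checks of 70-variant score sets across the three target
kinds.  The whole suite completes in well under a minute on one CPU.
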