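# mavekit

Local data model, validators and summaries for **multiplexed assays of
variant effect (MAVEs)**.

A MAVE measures the functional effect of thousands of variants of a gene,
regulatory region or other element in one pooled experiment, producing a
table of per-variant scores.  Sharing those tables requires strict,
checkable conventions: variant strings that validate against the target
sequence, a record hierarchy that preserves provenance, and stable bulk
archives.  `mavekit` implements that data model end to end so analysts and
submitters can run, locally and offline, the same checks a database
submission gate would apply:

- **MAVE-HGVS grammar** — a strictly validatable subset of HGVS variant
  nomenclature for targets without database reference sequences.
  Substitution (`c.1A>G`, `p.Trp24Cys`), deletion, duplication, insertion,
  delins, the target-identical variant (`c.=`) and multi-event variants
  (`c.[1A>G;5del]`) under `g.`/`c.`/`n.`/`p.`, with canonical round-trips
  and character-precise errors.
- **Target consistency** — every stated reference residue is checked
  against the score set's own target sequence (protein variants against a
  coding target via standard-codon-table translation), or against a
  transcript/genome accession through a pluggable sequence lookup.
- **Record hierarchy** — experiment sets ⊃ experiments ⊃ score sets with
  `urn:mavedb:NNNNNNNN[-x[-k[#v]]]` accessions, primary/secondary
  references, and meta-analysis score sets that combine or transform
  existing scores without modifying their sources.
- **Table schema validation** — reserved columns `hgvs_nt`, `hgvs_splice`,
  `hgvs_pro`, `score`; numeric extra columns; duplicate detection; paired
  count-table consistency.
- **Bulk archives** — one `metadata.json` plus a directory of CSV score and
  count tables, byte-stable and losslessly round-trippable.
- **Summaries** — score histograms (Freedman–Diaconis binning) and
  variant-effect heatmap matrices (22 rows at the protein level, 5 at the
  nucleotide level for non-coding targets), with strict conservation
  accounting.
- **Synthetic data** — a deterministic generator for targets, score sets
  and collections, including controlled defect seeding, so everything is
  testable with no downloads.

## Worked example

```python
from mavekit import (GeneratorSpec, make_target, make_score_set,
                     validate_score_table)

spec = GeneratorSpec(seed=11, n_variants=50, multi_variant_fraction=0.0,
                     defects=(("REF_MISMATCH", 2), ("DUPLICATE_VARIANT", 1)))
target = make_target(spec)
scores, counts = make_score_set(spec, target)
report = validate_score_table(scores, target)
print(report.valid)
for f in report.errors():
    print(f.code, f.row, f.message)
```

prints

```
False
REF_MISMATCH 10 variant states Ile at position 2 but target has Thr
REF_MISMATCH 46 variant states His at position 8 but target has Asn
DUPLICATE_VARIANT 50 row repeats the variant tuple of row 37
```

Three defects were seeded into an otherwise clean 50-variant score set and
the validator reports exactly those three errors, naming the row, the
stated vs. actual residue and the position.  This one-finding-per-defect
exactness is the package's central tested property.

The `examples/` directory has one short script per capability (parsing and
target checks, table validation, summaries, archive round-trips, the
meta-analysis hierarchy); each prints the numbers it computes and what
they mean.

## Command line

```bash
mavekit gen-fixture --seed 5 --out fixture/        # synthetic dataset
mavekit validate --scores fixture/scores.csv \
                 --counts fixture/counts.csv \
                 --target fixture/target.fasta     # exit 0/1/2
mavekit summarize --scores fixture/scores.csv \
                  --target fixture/target.fasta --out summary/ --images
mavekit load-archive --src fixture/archive --json
mavekit export-archive --src fixture/archive --out release/
```

Exit status 0 means no error findings, 1 means validation errors were
found, 2 means a usage or I/O problem.

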