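"""Validate a score/count table pair the way a submission gate would.

A generated score set with three deliberately seeded defects (two wrong
reference residues and one duplicated row) is validated; the validator
reports exactly those three errors with matching codes and row numbers.
"""

from mavekit import (
    GeneratorSpec,
    make_score_set,
    make_target,
    validate_count_consistency,
    validate_score_table,
)

spec = GeneratorSpec(
    seed=11, n_variants=50, multi_variant_fraction=0.0,
    defects=(("REF_MISMATCH", 2), ("DUPLICATE_VARIANT", 1)),
)
target = make_target(spec)
scores, counts = make_score_set(spec, target)

report = validate_score_table(scores, target)
report.extend(validate_count_consistency(scores, counts))

print(f"table: {scores.n_rows} rows, columns {scores.columns}")
print(f"valid: {report.valid}")
for f in report.errors():
    print(f"  {f.code} at row {f.row}: {f.message}")

# Three error findings, one per seeded defect — the exactness of this
# correspondence (k defects in, k matching findings out) is the property
# the validators are tested on.
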