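"""Parse MAVE-HGVS variant strings and check them against a target.

Variant strings in a score set must be syntactically canonical and state
reference residues that actually occur in the target sequence.  This
example parses a few strings, shows their structure, and validates them
against a short coding target.
"""

from mavekit import (
    MalformedVariant,
    TargetSequence,
    covered_positions,
    format_variant,
    parse_variant,
    validate_against_target,
)

for s in ("c.1A>G", "p.Trp24Cys", "c.[1A>G;5del]", "c.="):
    v = parse_variant(s)
    print(f"{s:18s} prefix={v.prefix} events={len(v.events)} "
          f"covered={sorted(covered_positions(v))} "
          f"round-trip={format_variant(v) == s}")

# identity must be written "=": a no-op substitution is a syntax error
try:
    parse_variant("c.1A>A")
except MalformedVariant as e:
    print(f"c.1A>A rejected: {e}")

# validate against a 9-nt coding target translating to Met-Trp-Cys
target = TargetSequence("demo", "nucleotide", "ATGTGGTGC", "coding")
for s in ("p.Trp2Cys", "p.Cys2Trp", "c.10A>G"):
    report = validate_against_target(parse_variant(s), target)
    codes = [f.code for f in report.findings] or ["(none)"]
    print(f"{s:12s} valid={report.valid} findings={codes}")

# The first variant matches the translated target (residue 2 is Trp), the
# second states the wrong reference residue, and the third points past the
# 9-nt target; the finding codes name each problem.
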