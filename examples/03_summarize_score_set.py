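"""Build the automatic summaries: score histogram and variant-effect map.

The histogram shows the typically bimodal score distribution
(loss-of-function near 0, wild-type-like near 1); the effect matrix has
one row per substitution (plus a deletion row) and one column per target
position.  Conservation laws tie both back to the table row count.
"""

from mavekit import (
    GeneratorSpec,
    effect_matrix,
    make_score_set,
    make_target,
    score_histogram,
    summary_stats,
)

spec = GeneratorSpec(seed=17, n_variants=300, target_length=90)
target = make_target(spec)
scores, _ = make_score_set(spec, target)

stats = summary_stats(scores)
print(f"{stats['n_variants']} variants, {stats['n_scored']} scored; "
      f"mean={stats['mean']:.3f} median={stats['median']:.3f}")

hist = score_histogram(scores)  # Freedman-Diaconis binning
print(f"histogram: {len(hist.counts)} bins over "
      f"[{hist.bin_edges[0]:.2f}, {hist.bin_edges[-1]:.2f}], "
      f"{hist.n_missing} missing; counts+missing={sum(hist.counts) + hist.n_missing}")

matrix = effect_matrix(scores, target)  # protein level for a coding target
print(f"effect map: {len(matrix.row_labels)} rows x "
      f"{len(matrix.col_positions)} positions, {matrix.n_filled} cells filled, "
      f"{matrix.n_excluded_multi} variants excluded (multi-event or no cell)")

# filled cells + excluded variants + single-site variants lacking a score
# always add up to the table's row count, so nothing is silently dropped.
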