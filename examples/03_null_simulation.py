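"""Null simulation: is the mined structure stronger than chance?

Generates a synthetic 34-comparison study carrying a planted 13-gene
pattern, then mines 50 randomized transaction sets under two nulls: a
plain resampling null (which preserves the pattern) and a label-shuffle
null (which destroys co-occurrence while keeping transaction sizes and
item frequencies).
"""

from larma.io_transactions import Comparison, build_transaction_set, filter_lncrna
from larma.nullsim import simulate_null, summarize
from larma.synth import generate_study, thirteen_gene_study_spec

study = generate_study(thirteen_gene_study_spec(seed=42))
comps = [
    Comparison(c.comparison_id, c.dataset_id, c.label,
               filter_lncrna(c.records, study.catalog))
    for c in study.comparisons
]
ts = build_transaction_set(comps)

for null in ("sample", "shuffle"):
    runs = simulate_null(ts, n_draw=34, n_runs=50, min_support=0.15,
                         min_confidence=1.0, seed=7, null=null)
    s = summarize(runs, rule_count_threshold=10_000, size_threshold=10)
    print(f"{null:>8} null: runs with a rule of >10 genes: "
          f"{s.count_maxsize_exceeding}/{s.n_runs}; "
          f"median max rule size {s.maxsize_quantiles[0.5]:.0f}")
# The resampling null keeps drawing the planted carriers, so large rules
# persist; the shuffle null rarely produces any rule beyond a pair,
# showing the pattern is not explained by item frequencies alone.
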