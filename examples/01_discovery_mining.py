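"""Mine the packaged discovery matrix for frequent lncRNA rules.

Encodes the six discovery comparisons (five brain-tumour grades vs
normal brain, one ovarian-cancer comparison) as transactions, mines
frequent itemsets at support >= 0.15 with confidence 1, and collapses
the redundant rules.
"""

from larma import datasets
from larma.mining import (
    generate_rules,
    min_support_count,
    mine_frequent_itemsets,
    remove_redundant,
)

ts = datasets.discovery_transactions(lfc_min=1.0, fdr_max=0.05)
print(f"{ts.n} transactions; at the full meta-analysis scale a 0.15 "
      f"support fraction means >= {min_support_count(0.15, 34)} of 34 comparisons")

itemsets = mine_frequent_itemsets(ts, min_support=0.15)
rules = generate_rules(itemsets, ts, min_confidence=1.0)
kept = remove_redundant(rules)

print(f"{len(itemsets)} frequent itemsets, {rules.n_rules} redundant rules, "
      f"{len(kept)} non-redundant")
top = kept[0]
print(f"maximal rule: {len(top.items)} lncRNAs in "
      f"{top.support_count}/{ts.n} comparisons")
print(" ", ", ".join(top.items))
# Every gene of this set is differentially expressed together in all six
# comparisons, so every rule over any subset holds with confidence 1 and
# the largest set subsumes the rest.
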