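"""Frequent-itemset and association-rule mining over transaction sets.

Exact levelwise Apriori with bitset support counting: each item maps to an
integer bitmask over transactions, so the support count of an itemset is
the popcount of the AND of its item masks. Counts are exact integers.

The redundancy reduction implemented here keeps, within every family of
rules spanning the same genes or a subset of them at equal support, only
the largest gene set — equivalently, the rule-bearing itemsets that are
*closed* with respect to the other rule-bearing itemsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .io_transactions import TransactionSet

__all__ = [
    "Itemset",
    "AssociationRule",
    "RuleSet",
    "min_support_count",
    "mine_frequent_itemsets",
    "generate_rules",
    "remove_redundant",
]


@dataclass(frozen=True)
class Itemset:
    """A gene set with its exact transaction support."""

    items: tuple[str, ...]
    support_count: int
    support: float

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class AssociationRule:
    """Rule X => C: if X is differentially expressed, so is C."""

    antecedent: tuple[str, ...]
    consequent: tuple[str, ...]
    support_count: int
    support: float
    confidence: float

    @property
    def union(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.antecedent) | set(self.consequent)))


@dataclass
class RuleSet:
    """Rules passing both thresholds, plus their distinct union itemsets."""

    rules: list[AssociationRule]
    itemsets: list[Itemset]  # distinct unions X ∪ C with supports
    min_support: float
    min_confidence: float

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    def max_itemset_size(self) -> int:
        return max((len(s) for s in self.itemsets), default=0)


def min_support_count(min_support: float, n: int) -> int:
    """Smallest count c with c/n >= min_support, i.e. ceil(min_support*n).

    A relative guard of 1e-9 absorbs binary-float round-up so that e.g.
    (0.15, 40) gives 6 rather than 7, and (6/34, 34) gives 6.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return max(1, math.ceil(min_support * n * (1.0 - 1e-9)))


def _item_masks(ts: TransactionSet) -> dict[str, int]:
    masks: dict[str, int] = {}
    for i, t in enumerate(ts):
        bit = 1 << i
        for g in t.items:
            masks[g] = masks.get(g, 0) | bit
    return masks


def _sort_key(itemset: Itemset):
    return (-len(itemset.items), -itemset.support_count, itemset.items)


def mine_frequent_itemsets(
    ts: TransactionSet, min_support: float
) -> list[Itemset]:
    """All itemsets (size >= 1) with support >= ``min_support``, exactly.

    Levelwise Apriori: level-k candidates join two frequent (k-1)-sets
    sharing a (k-2)-prefix and are pruned unless all their (k-1)-subsets
    are frequent (anti-monotonicity); surviving candidates are counted
    against the transaction bitmasks. Output is ordered by descending
    size, then descending support, then lexicographic items.
    """
    if not 0.0 < min_support <= 1.0:
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    if ts.n == 0:
        raise ValueError("transaction set is empty")
    n = ts.n
    minc = min_support_count(min_support, n)
    masks = _item_masks(ts)

    level: dict[tuple[str, ...], int] = {
        (g,): m for g, m in masks.items() if m.bit_count() >= minc
    }
    out: list[Itemset] = [
        Itemset(k, m.bit_count(), m.bit_count() / n) for k, m in level.items()
    ]
    while level:
        keys = sorted(level)
        next_level: dict[tuple[str, ...], int] = {}
        frequent = set(keys)
        # prefix-join: sorted keys sharing all but the last item are adjacent
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                if a[:-1] != b[:-1]:
                    break
                cand = a + (b[-1],)
                if any(
                    cand[:j] + cand[j + 1 :] not in frequent
                    for j in range(len(cand) - 2)
                ):
                    continue
                mask = level[a] & masks[cand[-1]]
                if mask.bit_count() >= minc:
                    next_level[cand] = mask
        out.extend(
            Itemset(k, m.bit_count(), m.bit_count() / n)
            for k, m in next_level.items()
        )
        level = next_level
    out.sort(key=_sort_key)
    return out


def generate_rules(
    itemsets: Sequence[Itemset],
    ts: TransactionSet,
    min_confidence: float,
    all_consequents: bool = False,
) -> RuleSet:
    """Emit rules X => C from the frequent itemsets.

    Default dialect: C is a single item of each frequent S with |S| >= 2
    and X = S \\ C. With ``all_consequents=True`` every nonempty
    bipartition of S is emitted. Confidence is supp(S)/supp(X); rules
    below ``min_confidence`` are dropped. The antecedent's support is
    looked up among the mined itemsets, which must be complete for the
    support threshold.
    """
    n = ts.n
    count_of = {s.items: s.support_count for s in itemsets}
    rules: list[AssociationRule] = []
    unions: dict[tuple[str, ...], int] = {}
    for s in itemsets:
        k = len(s.items)
        if k < 2:
            continue
        sizes = range(1, k) if all_consequents else (1,)
        emitted = False
        for csize in sizes:
            for cons in combinations(s.items, csize):
                ante = tuple(g for g in s.items if g not in cons)
                ante_count = count_of.get(ante)
                if ante_count is None:
                    raise ValueError(
                        "antecedent support missing: itemset list incomplete"
                    )
                conf = s.support_count / ante_count
                if conf >= min_confidence:
                    rules.append(
                        AssociationRule(
                            antecedent=ante,
                            consequent=cons,
                            support_count=s.support_count,
                            support=s.support_count / n,
                            confidence=conf,
                        )
                    )
                    emitted = True
        if emitted:
            unions[s.items] = s.support_count
    rule_itemsets = sorted(
        (Itemset(k, c, c / n) for k, c in unions.items()), key=_sort_key
    )
    # min_support of the RuleSet records the threshold the itemsets came from
    min_sup = min((s.support for s in itemsets), default=0.0)
    return RuleSet(
        rules=rules,
        itemsets=rule_itemsets,
        min_support=min_sup,
        min_confidence=min_confidence,
    )


def remove_redundant(rs: RuleSet) -> list[Itemset]:
    """Reduce a rule set to its non-redundant itemsets.

    Rules are grouped by their union gene set S; S is discarded when some
    retained rule-bearing T strictly contains S at the same support (the
    larger set subsumes it). The survivors form an antichain under
    (subset with equal support). Output ordering: descending size, then
    descending support, then lexicographic items — which also breaks any
    size ties deterministically.
    """
    kept: list[Itemset] = []
    kept_by_support: dict[int, list[frozenset[str]]] = {}
    # Descending size: any strict equal-support superset of S is either
    # already kept or subsumed by a kept superset that also contains S,
    # so testing against kept sets alone is exact.
    for s in sorted(rs.itemsets, key=_sort_key):
        fs = frozenset(s.items)
        if not any(
            fs < kt for kt in kept_by_support.get(s.support_count, ())
        ):
            kept.append(s)
            kept_by_support.setdefault(s.support_count, []).append(fs)
    return kept
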