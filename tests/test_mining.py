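import numpy as np
import pytest

from conftest import make_ts
from larma.mining import (
    generate_rules,
    min_support_count,
    mine_frequent_itemsets,
    remove_redundant,
)
from oracles import (
    brute_force_frequent_itemsets,
    brute_force_nonredundant,
    brute_force_rules,
    random_baskets,
)


class TestMinSupportCount:
    @pytest.mark.parametrize(
        "min_support,n,expected",
        [(0.15, 34, 6), (1.0, 10, 10), (0.15, 40, 6), (0.5, 3, 2), (0.01, 1, 1)],
    )
    def test_smallest_count_reaching_fraction(self, min_support, n, expected):
        c = min_support_count(min_support, n)
        assert c == expected
        assert c / n >= min_support
        assert (c - 1) / n < min_support or c == 1


class TestMineFrequentItemsets:
    def test_dense_discovery_block_is_complete(self, discovery_ts):
        # all six baskets share the same 13 genes, so every nonempty
        # subset is frequent at min count 6: 2^13 - 1 itemsets
        out = mine_frequent_itemsets(discovery_ts, 0.15)
        assert len(out) == 2**13 - 1
        assert all(s.support_count == 6 for s in out)
        assert max(len(s) for s in out) == 13

    def test_single_transaction(self):
        ts = make_ts([{"A"}])
        out = mine_frequent_itemsets(ts, 1.0)
        assert [(s.items, s.support_count) for s in out] == [(("A",), 1)]

    def test_bad_support_raises(self, discovery_ts):
        with pytest.raises(ValueError):
            mine_frequent_itemsets(discovery_ts, 0.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        baskets = random_baskets(rng, n_transactions=50, n_items=20, basket_size=8)
        ts = make_ts(baskets)
        minc = min_support_count(0.2, ts.n)
        mined = {frozenset(s.items): s.support_count
                 for s in mine_frequent_itemsets(ts, 0.2)}
        oracle = brute_force_frequent_itemsets(baskets, minc)
        assert mined == oracle

    @pytest.mark.parametrize("seed", [100, 101, 102])
    def test_anti_monotone_support(self, seed):
        rng = np.random.default_rng(seed)
        ts = make_ts(random_baskets(rng, 40, 15, 7))
        support = {frozenset(s.items): s.support_count
                   for s in mine_frequent_itemsets(ts, 0.1)}
        for fs, c in support.items():
            for g in fs:
                sub = fs - {g}
                if sub:
                    assert support[sub] >= c


class TestGenerateRules:
    def test_confidence_is_support_ratio(self):
        ts = make_ts([{"A", "B"}, {"A"}, {"C"}, {"D"}])
        itemsets = mine_frequent_itemsets(ts, 0.25)
        rs = generate_rules(itemsets, ts, min_confidence=0.0)
        rule = next(r for r in rs.rules if r.antecedent == ("A",))
        assert rule.consequent == ("B",)
        assert rule.confidence == pytest.approx(0.5)  # 0.25 / 0.5
        assert rule.support == pytest.approx(0.25)

    def test_dense_discovery_block_all_confidence_one(self, discovery_ts):
        itemsets = mine_frequent_itemsets(discovery_ts, 0.15)
        rs = generate_rules(itemsets, discovery_ts, 1.0)
        assert all(r.confidence == 1.0 for r in rs.rules)
        # every size>=2 subset S emits |S| single-consequent rules
        assert rs.n_rules == sum(
            k * len([s for s in itemsets if len(s.items) == k])
            for k in range(2, 14)
        )

    @pytest.mark.parametrize("seed,conf", [(7, 0.6), (8, 1.0), (9, 0.8)])
    def test_all_consequents_matches_bipartition_enumeration(self, seed, conf):
        rng = np.random.default_rng(seed)
        baskets = random_baskets(rng, 30, 12, 6)
        ts = make_ts(baskets)
        itemsets = mine_frequent_itemsets(ts, 0.15)
        rs = generate_rules(itemsets, ts, conf, all_consequents=True)
        got = {(frozenset(r.antecedent), frozenset(r.consequent)) for r in rs.rules}
        oracle = brute_force_rules(
            brute_force_frequent_itemsets(baskets, min_support_count(0.15, ts.n)),
            ts.n, conf, single_consequent=False,
        )
        assert got == oracle

    def test_confidence_one_rules_have_equal_support_subset(self, discovery_ts):
        itemsets = mine_frequent_itemsets(discovery_ts, 0.15)
        support = {frozenset(s.items): s.support_count for s in itemsets}
        rs = generate_rules(itemsets, discovery_ts, 1.0)
        for r in rs.rules:
            s = frozenset(r.union)
            assert support[frozenset(r.antecedent)] == support[s]


class TestRemoveRedundant:
    def test_discovery_block_reduces_to_single_maximal_set(self, discovery_ts):
        itemsets = mine_frequent_itemsets(discovery_ts, 0.15)
        rs = generate_rules(itemsets, discovery_ts, 1.0)
        kept = remove_redundant(rs)
        assert len(kept) == 1
        assert len(kept[0].items) == 13
        assert kept[0].support_count == 6

    def test_different_supports_both_retained(self):
        # {A,B} in 5 baskets, {A,B,C} in 3: supports differ, no subsumption
        baskets = [{"A", "B", "C"}] * 3 + [{"A", "B"}] * 2 + [{"D"}] * 5
        ts = make_ts(baskets)
        itemsets = mine_frequent_itemsets(ts, 0.2)
        rs = generate_rules(itemsets, ts, 1.0)
        kept = {frozenset(s.items): s.support_count for s in remove_redundant(rs)}
        assert kept[frozenset("ABC")] == 3
        assert kept[frozenset("AB")] == 5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_closed_itemset_filter(self, seed):
        rng = np.random.default_rng(1000 + seed)
        baskets = random_baskets(rng, 40, 14, 7)
        ts = make_ts(baskets)
        itemsets = mine_frequent_itemsets(ts, 0.1)
        rs = generate_rules(itemsets, ts, 1.0)
        kept = {frozenset(s.items) for s in remove_redundant(rs)}
        unions = {frozenset(s.items): s.support_count for s in rs.itemsets}
        assert kept == brute_force_nonredundant(unions)

    @pytest.mark.parametrize("seed", [42, 43])
    def test_output_is_antichain_under_equal_support_inclusion(self, seed):
        rng = np.random.default_rng(seed)
        ts = make_ts(random_baskets(rng, 50, 16, 8))
        rs = generate_rules(
            mine_frequent_itemsets(ts, 0.1), ts, 0.9
        )
        kept = [(frozenset(s.items), s.support_count) for s in remove_redundant(rs)]
        for i, (s1, c1) in enumerate(kept):
            for s2, c2 in kept[i + 1:]:
                assert not (c1 == c2 and (s1 < s2 or s2 < s1))
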