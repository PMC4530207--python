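import math

import numpy as np
import pytest

from conftest import make_ts
from larma.comodulation import (
    CopresenceTable,
    PlatformUniverse,
    common_genes,
    comodulate,
    copresence_table,
)
from oracles import indicator_phi


def table_vectors(tab: CopresenceTable):
    """Expand a 2x2 into the two 0/1 indicator vectors it summarizes."""
    a = [1] * tab.n11 + [1] * tab.n10 + [0] * tab.n01 + [0] * tab.n00
    b = [1] * tab.n11 + [0] * tab.n10 + [1] * tab.n01 + [0] * tab.n00
    return np.array(a), np.array(b)


class TestCopresenceTable:
    def test_hand_built_table_phi_matches_indicator_pearson(self):
        tab = CopresenceTable(n11=8, n10=2, n01=3, n00=7)
        assert tab.N == 20
        a, b = table_vectors(tab)
        assert tab.phi() == pytest.approx(indicator_phi(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_tables_phi_and_chi2_identities(self, seed):
        rng = np.random.default_rng(seed)
        n11, n10, n01, n00 = rng.integers(0, 12, size=4)
        tab = CopresenceTable(int(n11), int(n10), int(n01), int(n00))
        phi = tab.phi()
        if not tab.margins_positive():
            assert math.isnan(phi)
            return
        a, b = table_vectors(tab)
        assert phi == pytest.approx(indicator_phi(a, b), abs=1e-12)
        assert tab.chi2() == pytest.approx(tab.N * phi**2, abs=1e-12)

    def test_zero_margin_reports_nan(self):
        assert math.isnan(CopresenceTable(5, 0, 3, 0).phi())


def cohort(n_comparisons=20, seed=0, n_items=30, rate=0.3):
    """Random signed cohort over a full shared universe."""
    rng = np.random.default_rng(seed)
    items = [f"G{i:02d}" for i in range(n_items)]
    baskets, signs = [], []
    for _ in range(n_comparisons):
        basket = {g for g in items if rng.random() < rate}
        baskets.append(basket)
        signs.append({g: (1 if rng.random() < 0.5 else -1) for g in basket})
    ts = make_ts(baskets, signs)
    uni = PlatformUniverse({t.comparison_id: items for t in ts})
    return ts, uni


class TestComodulate:
    def test_perfect_association_phi_one(self):
        # candidate mirrors the target in all 12 copresent comparisons
        # where the target is down, absent in the other 8
        baskets = [{"T", "C"}] * 12 + [{"X"}] * 8
        signs = [{"T": -1, "C": 1} for _ in range(12)] + [{"X": 1}] * 8
        ts = make_ts(baskets, signs)
        uni = PlatformUniverse({t.comparison_id: {"T", "C", "X"} for t in ts})
        res = comodulate("T", -1, ts, uni, min_copresence=10, min_correlation=0.3)
        by_gene = {r.candidate: r for r in res}
        assert by_gene["C"].phi == pytest.approx(1.0)
        assert by_gene["C"].copresence == 20

    def test_low_copresence_filtered(self):
        ts, _ = cohort()
        # candidate measurable in only 5 comparisons
        ids = [t.comparison_id for t in ts]
        universes = {cid: {"G00", "G01"} if i < 5 else {"G00"} for i, cid in enumerate(ids)}
        res = comodulate("G00", 1, ts, PlatformUniverse(universes), min_copresence=10,
                         min_correlation=-2.0)
        assert all(r.candidate != "G01" for r in res)

    def test_wrong_sign_target_not_counted(self):
        baskets = [{"T", "C"}] * 10
        signs = [{"T": 1, "C": 1}] * 5 + [{"T": -1, "C": 1}] * 5
        ts = make_ts(baskets, signs)
        uni = PlatformUniverse({t.comparison_id: {"T", "C"} for t in ts})
        tab = copresence_table("T", 1, "C", ts, uni)
        assert (tab.n11, tab.n01) == (5, 5)

    def test_results_invariant_to_transaction_order(self):
        ts, uni = cohort(seed=5)
        rev = make_ts(
            [t.items for t in reversed(ts.transactions)],
            [dict(t.sign_of) for t in reversed(ts.transactions)],
        )
        uni_rev = PlatformUniverse({t.comparison_id: uni.all_genes() for t in rev})
        a = comodulate("G00", 1, ts, uni, min_copresence=5, min_correlation=-2.0)
        b = comodulate("G00", 1, rev, uni_rev, min_copresence=5, min_correlation=-2.0)
        assert [(r.candidate, r.phi) for r in a] == [(r.candidate, r.phi) for r in b]

    def test_ranking_is_phi_descending(self):
        ts, uni = cohort(seed=9)
        res = comodulate("G00", 1, ts, uni, min_copresence=5, min_correlation=-2.0)
        phis = [r.phi for r in res]
        assert phis == sorted(phis, reverse=True)

    def test_unmeasurable_target_raises(self):
        ts, _ = cohort()
        uni = PlatformUniverse({t.comparison_id: {"OTHER"} for t in ts})
        with pytest.raises(ValueError):
            comodulate("G00", 1, ts, uni)


class TestCommonGenes:
    def test_gene_in_all_lists_included(self):
        lists = [["A", "B"], ["A"], ["A", "C"]]
        assert "A" in common_genes(lists, 3)

    def test_threshold_counting(self):
        lists = [{"A", "B"}, {"B", "C"}, {"B"}]
        assert common_genes(lists, 2) == {"B"}

    def test_planted_pan_list_genes_recovered(self):
        rng = np.random.default_rng(4)
        planted = {f"P{i:02d}" for i in range(50)}
        lists = []
        for k in range(10):
            noise = {f"N{k}_{i}" for i in range(rng.integers(5, 30))}
            drop = set() if k else {f"P{i:02d}" for i in range(5)}  # miss 1 list
            lists.append((planted - drop) | noise)
        assert common_genes(lists, 9) == planted

    def test_min_lists_bound(self):
        with pytest.raises(ValueError):
            common_genes([["A"]], 2)
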