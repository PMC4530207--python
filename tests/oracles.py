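"""Independent brute-force oracles used to cross-check the implementation.

Everything here enumerates exhaustively or recomputes from first
principles and is deliberately ignorant of the package's algorithms.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def brute_force_frequent_itemsets(
    baskets: list[frozenset[str]], min_count: int
) -> dict[frozenset[str], int]:
    """Support of every itemset meeting ``min_count``, by enumerating all
    subsets of every transaction (any frequent set is a subset of some
    transaction)."""
    counts: dict[frozenset[str], int] = {}
    for basket in baskets:
        items = sorted(basket)
        for r in range(1, len(items) + 1):
            for combo in combinations(items, r):
                fs = frozenset(combo)
                counts[fs] = counts.get(fs, 0) + 1
    return {fs: c for fs, c in counts.items() if c >= min_count}


def brute_force_rules(
    frequent: dict[frozenset[str], int],
    n: int,
    min_confidence: float,
    single_consequent: bool,
) -> set[tuple[frozenset[str], frozenset[str]]]:
    """All (antecedent, consequent) bipartitions passing the confidence
    threshold, derived purely from the support table."""
    rules = set()
    for s, c_s in frequent.items():
        if len(s) < 2:
            continue
        items = sorted(s)
        sizes = [1] if single_consequent else range(1, len(items))
        for csize in sizes:
            for cons in combinations(items, csize):
                cons_fs = frozenset(cons)
                ante = s - cons_fs
                if c_s / frequent[ante] >= min_confidence:
                    rules.add((ante, cons_fs))
    return rules


def brute_force_nonredundant(
    rule_unions: dict[frozenset[str], int]
) -> set[frozenset[str]]:
    """Keep S iff no strict superset among the rule unions has equal
    support (the equal-support-superset filter)."""
    return {
        s
        for s, c in rule_unions.items()
        if not any(c == c2 and s < s2 for s2, c2 in rule_unions.items())
    }


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values: adj_i = min_{j>=i} p_(j)*m/j,
    clipped at 1, mapped back to input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj_sorted[rank - 1] = running
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = adj_sorted[rank]
    return out


def hypergeom_upper_tail(k: int, M: int, n: int, N: int) -> float:
    """P(overlap >= k) by direct summation of hypergeometric masses."""
    total = 0.0
    for x in range(k, min(n, N) + 1):
        total += (
            math.comb(n, x) * math.comb(M - n, N - x) / math.comb(M, N)
        )
    return min(total, 1.0)


def indicator_phi(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two 0/1 indicator vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.corrcoef(a, b)[0, 1])


def random_baskets(
    rng: np.random.Generator,
    n_transactions: int,
    n_items: int,
    basket_size: int,
) -> list[frozenset[str]]:
    items = [f"I{i:02d}" for i in range(n_items)]
    out = []
    for _ in range(n_transactions):
        k = int(rng.integers(1, min(basket_size, n_items) + 1))
        out.append(frozenset(rng.choice(items, size=k, replace=False)))
    return out
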