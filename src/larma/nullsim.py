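"""Permutation/resampling null model for the mined rule statistics.

The observed mining output (how many redundant rules, how large the
largest rule) is compared against repeated mining runs on randomized
transaction sets. Two nulls are available:

* ``sample`` — draw ``n_draw`` transactions without replacement from a
  user-supplied pool of comparisons and mine them with the same
  thresholds.
* ``shuffle`` — additionally destroy item co-occurrence before mining by
  swap randomization: repeated pairwise swaps of (transaction, item)
  incidences, preserving every transaction's size and approximately each
  item's overall frequency.

Both are driven by a single integer seed and fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_transactions import Transaction, TransactionSet
from .mining import generate_rules, mine_frequent_itemsets

__all__ = ["SimulationRun", "NullSummary", "simulate_null", "summarize",
           "shuffle_items"]


@dataclass(frozen=True)
class SimulationRun:
    """Statistics of one null mining run."""

    run_index: int
    n_redundant_rules: int
    max_itemset_size: int  # 0 when no rule was produced

    def __post_init__(self) -> None:
        if self.n_redundant_rules > 0 and self.max_itemset_size < 2:
            raise ValueError("rules imply a max itemset size of at least 2")


@dataclass
class NullSummary:
    """Exceedance counts and empirical distributions over the runs."""

    n_runs: int
    rule_count_threshold: int
    size_threshold: int
    count_rules_exceeding: int
    count_maxsize_exceeding: int
    rule_count_quantiles: dict[float, float]
    maxsize_quantiles: dict[float, float]
    rule_count_distribution: dict[int, int] = field(default_factory=dict)
    maxsize_distribution: dict[int, int] = field(default_factory=dict)


def shuffle_items(
    ts: TransactionSet, rng: np.random.Generator, swaps_per_incidence: int = 10
) -> TransactionSet:
    """Swap-randomize item labels across transactions.

    Picks two (transaction, item) incidences uniformly and exchanges
    their items whenever neither item already occurs in the other
    transaction; repeated ``swaps_per_incidence`` times the number of
    incidences. Transaction sizes are preserved exactly, item marginals
    approximately. Signs travel with the items.
    """
    baskets = [sorted(t.items) for t in ts]
    signs = [dict(t.sign_of) for t in ts]
    members = [set(b) for b in baskets]
    incid = [(i, j) for i, b in enumerate(baskets) for j in range(len(b))]
    if len(incid) < 2:
        return ts
    n_swaps = swaps_per_incidence * len(incid)
    for _ in range(n_swaps):
        a, b = rng.integers(0, len(incid), size=2)
        (ti, ii), (tj, jj) = incid[a], incid[b]
        if ti == tj:
            continue
        gi, gj = baskets[ti][ii], baskets[tj][jj]
        if gi == gj or gi in members[tj] or gj in members[ti]:
            continue
        baskets[ti][ii], baskets[tj][jj] = gj, gi
        members[ti].remove(gi)
        members[ti].add(gj)
        members[tj].remove(gj)
        members[tj].add(gi)
        si, sj = signs[ti].pop(gi), signs[tj].pop(gj)
        signs[ti][gj] = si
        signs[tj][gi] = sj
    txs = []
    for t, b, s in zip(ts, baskets, signs):
        txs.append(
            Transaction(
                comparison_id=t.comparison_id,
                items=frozenset(b),
                sign_of=s,
                lfc_of={g: float(v) for g, v in s.items()},
            )
        )
    return TransactionSet(txs)


def simulate_null(
    pool: TransactionSet,
    n_draw: int,
    n_runs: int,
    min_support: float,
    min_confidence: float,
    seed: int,
    null: str = "sample",
) -> list[SimulationRun]:
    """Mine ``n_runs`` randomized transaction sets drawn from ``pool``.

    Each run samples ``n_draw`` transactions without replacement (after
    swap randomization when ``null='shuffle'``), mines frequent itemsets
    and confidence-filtered rules at the given thresholds, and records
    the redundant-rule count (single-consequent dialect) and the largest
    rule itemset's size. Identical seeds give identical run lists.
    """
    if n_draw > pool.n:
        raise ValueError(f"pool has {pool.n} transactions, cannot draw {n_draw}")
    if null not in ("sample", "shuffle"):
        raise ValueError(f"unknown null model {null!r}")
    rng = np.random.default_rng(seed)
    runs: list[SimulationRun] = []
    for r in range(n_runs):
        base = shuffle_items(pool, rng) if null == "shuffle" else pool
        idx = rng.choice(pool.n, size=n_draw, replace=False)
        drawn = TransactionSet([base[i] for i in sorted(idx)])
        itemsets = mine_frequent_itemsets(drawn, min_support)
        rs = generate_rules(itemsets, drawn, min_confidence)
        runs.append(
            SimulationRun(
                run_index=r,
                n_redundant_rules=rs.n_rules,
                max_itemset_size=rs.max_itemset_size(),
            )
        )
    return runs


_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)


def summarize(
    runs: list[SimulationRun],
    rule_count_threshold: int,
    size_threshold: int,
) -> NullSummary:
    """Exceedance counts and empirical quantiles of the run statistics."""
    if not runs:
        raise ValueError("no runs to summarize")
    n_rules = np.array([r.n_redundant_rules for r in runs])
    sizes = np.array([r.max_itemset_size for r in runs])
    return NullSummary(
        n_runs=len(runs),
        rule_count_threshold=rule_count_threshold,
        size_threshold=size_threshold,
        count_rules_exceeding=int((n_rules > rule_count_threshold).sum()),
        count_maxsize_exceeding=int((sizes > size_threshold).sum()),
        rule_count_quantiles={
            q: float(np.quantile(n_rules, q)) for q in _QUANTILES
        },
        maxsize_quantiles={q: float(np.quantile(sizes, q)) for q in _QUANTILES},
        rule_count_distribution={
            int(v): int(c) for v, c in zip(*np.unique(n_rules, return_counts=True))
        },
        maxsize_distribution={
            int(v): int(c) for v, c in zip(*np.unique(sizes, return_counts=True))
        },
    )
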