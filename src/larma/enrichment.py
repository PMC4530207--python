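"""Gene-set over-representation with Benjamini-Hochberg correction.

Flat gene-set enrichment: for a query gene list and a collection of
gene sets restricted to a common universe, each set is tested for
over-representation with the one-sided Fisher exact test (equivalently
the hypergeometric upper tail), and p-values are adjusted across all
tested sets by the Benjamini-Hochberg step-up procedure. No ontology
structure is consulted — sets are supplied flat, GMT-style.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetCollection", "EnrichmentRow", "enrich", "read_gmt"]


class GeneSetCollection:
    """Named gene sets over an explicit gene universe.

    Members outside the universe are dropped on construction so that the
    hypergeometric model is well-posed.
    """

    def __init__(
        self,
        sets: Mapping[str, tuple[str, Iterable[str]]],
        universe: Iterable[str],
    ):
        self.universe = frozenset(universe)
        if not self.universe:
            raise ValueError("gene universe is empty")
        self.sets: dict[str, tuple[str, frozenset[str]]] = {
            sid: (name, frozenset(members) & self.universe)
            for sid, (name, members) in sets.items()
        }

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, sid: str) -> frozenset[str]:
        return self.sets[sid][1]


@dataclass(frozen=True)
class EnrichmentRow:
    set_id: str
    name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    adj_p: float
    significant: bool


def enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    adj_p_max: float = 0.05,
) -> list[EnrichmentRow]:
    """Over-representation of the query in every gene set.

    Query genes outside the universe are dropped with a warning. The
    upper-tail hypergeometric p for observing at least the seen overlap
    is adjusted by BH across all tested sets; ``significant`` flags
    adj_p strictly below ``adj_p_max``. Rows are ordered by (adj_p,
    set_id).
    """
    query = set(query)
    dropped = query - sets.universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes outside the universe were dropped",
            stacklevel=2,
        )
    query &= sets.universe
    M, N = len(sets.universe), len(query)

    sids = sorted(sets.sets)
    pvals = []
    for sid in sids:
        members = sets[sid]
        k, n = len(query & members), len(members)
        # P(overlap >= k) under sampling N of M without replacement
        pvals.append(float(hypergeom.sf(k - 1, M, n, N)))
    if not sids:
        return []
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    rows = [
        EnrichmentRow(
            set_id=sid,
            name=sets.sets[sid][0],
            overlap=len(query & sets[sid]),
            set_size=len(sets[sid]),
            query_size=N,
            universe_size=M,
            p=p,
            adj_p=float(a),
            significant=bool(a < adj_p_max),
        )
        for sid, p, a in zip(sids, pvals, adj)
    ]
    rows.sort(key=lambda r: (r.adj_p, r.set_id))
    return rows


def read_gmt(
    path: str | Path, universe: Iterable[str] | None = None
) -> GeneSetCollection:
    """Read a GMT file: ``set_id<TAB>description<TAB>gene1<TAB>gene2...``.

    When ``universe`` is None, the union of all set members is used.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    union: set[str] = set()
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sid, desc, members = fields[0], fields[1], frozenset(fields[2:])
            sets[sid] = (desc, members)
            union |= members
    return GeneSetCollection(sets, universe if universe is not None else union)
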