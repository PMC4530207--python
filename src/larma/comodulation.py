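"""Target-constrained pairwise comodulation over copresence universes.

For a fixed *target* gene with a required modulation sign, every other
gene is scored on the comparisons whose measurement platforms include
both genes (the *copresence* universe — platforms differ, so pairs are
only comparable where both are measurable). On that universe a 2x2
table is formed:

    n11  target modulated with the required sign AND candidate modulated
    n10  target modulated (required sign), candidate not
    n01  candidate modulated, target not
    n00  neither

from which support, confidence, lift, the 1-df chi-square statistic and
the phi coefficient (the "correlation index" used for ranking; it equals
the Pearson correlation of the two presence indicators) are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .io_transactions import TransactionSet

__all__ = [
    "PlatformUniverse",
    "CopresenceTable",
    "ComodResult",
    "copresence_table",
    "comodulate",
    "common_genes",
    "read_universes",
    "write_universes",
]


class PlatformUniverse:
    """comparison_id -> set of gene symbols measurable on its platform."""

    def __init__(self, universe_of: Mapping[str, Iterable[str]]):
        self._universe_of = {k: frozenset(v) for k, v in universe_of.items()}

    def __getitem__(self, comparison_id: str) -> frozenset[str]:
        return self._universe_of[comparison_id]

    def __contains__(self, comparison_id: str) -> bool:
        return comparison_id in self._universe_of

    def ids(self) -> list[str]:
        return list(self._universe_of)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for u in self._universe_of.values():
            out |= u
        return frozenset(out)

    def check_consistent(self, ts: TransactionSet) -> None:
        """Every transaction's items must lie within its universe."""
        for t in ts:
            if t.comparison_id not in self._universe_of:
                raise ValueError(f"no universe for {t.comparison_id}")
            extra = t.items - self._universe_of[t.comparison_id]
            if extra:
                raise ValueError(
                    f"{t.comparison_id}: items outside platform universe: "
                    f"{sorted(extra)[:5]}"
                )


@dataclass(frozen=True)
class CopresenceTable:
    """2x2 modulation counts over the copresent comparisons."""

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def N(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def margins_positive(self) -> bool:
        return (
            self.n11 + self.n10 > 0
            and self.n01 + self.n00 > 0
            and self.n11 + self.n01 > 0
            and self.n10 + self.n00 > 0
        )

    def phi(self) -> float:
        """Phi coefficient; NaN when a margin is zero."""
        if not self.margins_positive():
            return math.nan
        num = self.n11 * self.n00 - self.n10 * self.n01
        den = math.sqrt(
            (self.n11 + self.n10)
            * (self.n01 + self.n00)
            * (self.n11 + self.n01)
            * (self.n10 + self.n00)
        )
        return num / den

    def chi2(self) -> float:
        """1-df chi-square without continuity correction: N * phi^2."""
        phi = self.phi()
        return math.nan if math.isnan(phi) else self.N * phi * phi


@dataclass(frozen=True)
class ComodResult:
    candidate: str
    table: CopresenceTable
    support: float
    confidence: float
    lift: float
    chi2: float
    chi2_p: float
    phi: float
    candidate_sign: int  # majority sign among the n11 co-modulated comparisons

    @property
    def copresence(self) -> int:
        return self.table.N


def copresence_table(
    target: str,
    target_sign: int,
    candidate: str,
    ts: TransactionSet,
    universes: PlatformUniverse,
) -> CopresenceTable:
    """2x2 counts over comparisons where both genes are measurable.

    Target presence requires membership with the required sign; candidate
    presence is membership with any sign.
    """
    n11 = n10 = n01 = n00 = 0
    for t in ts:
        u = universes[t.comparison_id]
        if target not in u or candidate not in u:
            continue
        tgt = target in t.items and t.sign_of[target] == target_sign
        cand = candidate in t.items
        if tgt and cand:
            n11 += 1
        elif tgt:
            n10 += 1
        elif cand:
            n01 += 1
        else:
            n00 += 1
    return CopresenceTable(n11, n10, n01, n00)


def comodulate(
    target: str,
    target_sign: int,
    ts: TransactionSet,
    universes: PlatformUniverse,
    min_copresence: int = 10,
    min_correlation: float = 0.3,
    min_lift: float = 0.0,
    chi2_p_max: float = 1.0,
) -> list[ComodResult]:
    """Rank candidate genes comodulated with a sign-constrained target.

    Candidates passing copresence >= ``min_copresence``, phi >
    ``min_correlation``, lift >= ``min_lift`` and chi-square p <=
    ``chi2_p_max`` are returned sorted by phi descending (ties by gene
    symbol). Candidates with a zero-margin 2x2 (phi undefined) are
    filtered out.
    """
    if target_sign not in (1, -1):
        raise ValueError("target_sign must be +1 or -1")
    measurable = any(
        target in universes[t.comparison_id] for t in ts if t.comparison_id in universes
    )
    if not measurable:
        raise ValueError(f"target {target!r} is not measurable in any comparison")

    results: list[ComodResult] = []
    for candidate in sorted(universes.all_genes() - {target}):
        tab = copresence_table(target, target_sign, candidate, ts, universes)
        if tab.N < min_copresence:
            continue
        phi = tab.phi()
        if math.isnan(phi) or phi <= min_correlation:
            continue
        n1_ = tab.n11 + tab.n10
        n_1 = tab.n11 + tab.n01
        support = tab.n11 / tab.N
        confidence = tab.n11 / n1_ if n1_ else math.nan
        lift = (tab.n11 * tab.N) / (n1_ * n_1) if n1_ and n_1 else math.nan
        if not math.isnan(lift) and lift < min_lift:
            continue
        chi2 = tab.chi2()
        p = float(stats.chi2.sf(chi2, df=1))
        if p > chi2_p_max:
            continue
        sign = _majority_candidate_sign(target, target_sign, candidate, ts, universes)
        results.append(
            ComodResult(
                candidate=candidate,
                table=tab,
                support=support,
                confidence=confidence,
                lift=lift,
                chi2=chi2,
                chi2_p=p,
                phi=phi,
                candidate_sign=sign,
            )
        )
    results.sort(key=lambda r: (-r.phi, r.candidate))
    return results


def _majority_candidate_sign(
    target: str,
    target_sign: int,
    candidate: str,
    ts: TransactionSet,
    universes: PlatformUniverse,
) -> int:
    """Majority sign of the candidate where it co-modulates with the target."""
    tally = 0
    for t in ts:
        u = universes[t.comparison_id]
        if target not in u or candidate not in u:
            continue
        if (
            target in t.items
            and t.sign_of[target] == target_sign
            and candidate in t.items
        ):
            tally += t.sign_of[candidate]
    return 1 if tally >= 0 else -1


def common_genes(
    lists: Sequence[Sequence[ComodResult] | Sequence[str]], min_lists: int
) -> set[str]:
    """Genes present in at least ``min_lists`` of the ranked lists."""
    if min_lists > len(lists):
        raise ValueError("min_lists exceeds the number of lists")
    counts: dict[str, int] = {}
    for lst in lists:
        genes = {
            r.candidate if isinstance(r, ComodResult) else str(r) for r in lst
        }
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= min_lists}


def read_universes(path: str | Path) -> PlatformUniverse:
    """Read ``comparison_id<TAB>gene1,gene2,...`` universe files."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cid, _, payload = line.partition("\t")
            out[cid] = set(payload.split(",")) if payload else set()
    return PlatformUniverse(out)


def write_universes(universes: PlatformUniverse, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid in universes.ids():
            fh.write(f"{cid}\t{','.join(sorted(universes[cid]))}\n")
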