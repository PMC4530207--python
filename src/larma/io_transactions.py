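"""Differential-expression tables, lncRNA filtering and transaction assembly.

A *transaction* is the market-basket encoding of one tumour-vs-normal
comparison: the set of lncRNA gene symbols called differentially expressed
in it, together with the sign and magnitude of each gene's representative
log2 fold change. Transaction sets are the input to the frequent-itemset
miner in :mod:`larma.mining`.

Gene symbols qualify as lncRNAs through a Gencode-style biotype whitelist
(antisense, lincRNA, processed_transcript, sense_intronic,
sense_overlapping, 3prime_overlapping_ncrna).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "LNCRNA_BIOTYPES",
    "DiffExprRecord",
    "Comparison",
    "AnnotationCatalog",
    "Transaction",
    "TransactionSet",
    "ColumnMap",
    "filter_lncrna",
    "build_transaction",
    "build_transaction_set",
    "read_de_table",
    "read_annotation",
    "write_baskets",
    "read_baskets",
]

#: Gencode transcript biotypes counted as long noncoding RNA.
LNCRNA_BIOTYPES = frozenset(
    {
        "3prime_overlapping_ncrna",
        "antisense",
        "lincRNA",
        "processed_transcript",
        "sense_intronic",
        "sense_overlapping",
    }
)


class BasketParseError(ValueError):
    """Raised on a malformed basket line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


@dataclass(frozen=True)
class DiffExprRecord:
    """One probe-level differential-expression call.

    Parameters
    ----------
    probe_id : str
        Platform probe identifier.
    gene_symbol : str
        HGNC-style gene symbol the probe maps to.
    lfc : float
        log2 fold change (tumour over normal).
    adj_p : float
        FDR-adjusted p-value, in [0, 1].
    """

    probe_id: str
    gene_symbol: str
    lfc: float
    adj_p: float

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if not math.isfinite(self.lfc):
            raise ValueError(f"lfc must be finite, got {self.lfc!r}")
        if not 0.0 <= self.adj_p <= 1.0:
            raise ValueError(f"adj_p must be in [0, 1], got {self.adj_p!r}")


@dataclass
class Comparison:
    """One pairwise comparison (e.g. tumour grade vs normal) of a dataset."""

    comparison_id: str
    dataset_id: str
    label: str
    records: list[DiffExprRecord] = field(default_factory=list)


class AnnotationCatalog:
    """Gene symbol -> biotype lookup with an lncRNA whitelist test."""

    def __init__(self, biotype_of: Mapping[str, str]):
        self._biotype_of = dict(biotype_of)

    def __len__(self) -> int:
        return len(self._biotype_of)

    def __contains__(self, gene: str) -> bool:
        return gene in self._biotype_of

    def biotype(self, gene: str) -> str | None:
        return self._biotype_of.get(gene)

    def is_lncrna(self, gene: str) -> bool:
        return self._biotype_of.get(gene) in LNCRNA_BIOTYPES

    @property
    def lncrna_genes(self) -> frozenset[str]:
        return frozenset(
            g for g, b in self._biotype_of.items() if b in LNCRNA_BIOTYPES
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationCatalog":
        """Read a two-column gene<TAB>biotype table (no header required)."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two tab-separated columns")
        first = df.iloc[0]
        if str(first[0]).lower() in {"gene", "gene_symbol", "symbol"}:
            df = df.iloc[1:]
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    _GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')

    @classmethod
    def from_gtf(cls, path: str | Path) -> "AnnotationCatalog":
        """Extract gene_name -> biotype from a Gencode-dialect GTF.

        A gene qualifies as lncRNA if ANY of its transcripts carries a
        whitelisted biotype; the whitelisted biotype wins over others seen
        for the same symbol.
        """
        biotype_of: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    continue
                attrs = dict(cls._GTF_ATTR.findall(fields[8]))
                name = attrs.get("gene_name")
                if name is None:
                    continue
                biotype = (
                    attrs.get("transcript_type")
                    or attrs.get("transcript_biotype")
                    or attrs.get("gene_type")
                    or attrs.get("gene_biotype")
                )
                if biotype is None:
                    continue
                if name not in biotype_of or biotype in LNCRNA_BIOTYPES:
                    biotype_of[name] = biotype
        return cls(biotype_of)


@dataclass(frozen=True)
class Transaction:
    """Item basket of one comparison: DE gene symbols with signed LFCs.

    ``items`` always equals the key set of ``sign_of`` and ``lfc_of``;
    ``sign_of[g]`` is the sign of ``lfc_of[g]``, the representative
    (maximum-|LFC|) passing probe of gene ``g``.

    Equality and hashing consider ``comparison_id``, ``items`` and
    ``sign_of`` only: the representative magnitudes are auxiliary and are
    not preserved by the basket serialization round trip.
    """

    comparison_id: str
    items: frozenset[str]
    sign_of: Mapping[str, int]
    lfc_of: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.items != set(self.sign_of) or self.items != set(self.lfc_of):
            raise ValueError("items, sign_of and lfc_of must share keys")
        for g in self.items:
            if self.sign_of[g] not in (1, -1):
                raise ValueError(f"sign_of[{g}] must be +1 or -1")
            if self.sign_of[g] != (1 if self.lfc_of[g] > 0 else -1):
                raise ValueError(f"sign_of[{g}] inconsistent with lfc_of")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Transaction):
            return NotImplemented
        return (
            self.comparison_id == other.comparison_id
            and self.items == other.items
            and dict(self.sign_of) == dict(other.sign_of)
        )

    def __hash__(self) -> int:
        return hash((self.comparison_id, self.items))

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class TransactionSet:
    """Ordered collection of transactions with unique comparison ids."""

    transactions: list[Transaction]

    def __post_init__(self) -> None:
        ids = [t.comparison_id for t in self.transactions]
        if len(set(ids)) != len(ids):
            raise ValueError("comparison_ids must be unique")

    @property
    def n(self) -> int:
        return len(self.transactions)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.transactions)

    def __getitem__(self, i):
        return self.transactions[i]

    def item_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.transactions:
            out |= t.items
        return frozenset(out)


def filter_lncrna(
    records: Sequence[DiffExprRecord], catalog: AnnotationCatalog
) -> list[DiffExprRecord]:
    """Keep records whose gene symbol maps to a whitelisted lncRNA biotype.

    Order is preserved; an empty catalog is a configuration error.
    """
    if len(catalog) == 0:
        raise ValueError("annotation catalog is empty")
    return [r for r in records if catalog.is_lncrna(r.gene_symbol)]


def build_transaction(
    comp: Comparison, lfc_min: float = 1.0, fdr_max: float = 0.05
) -> Transaction:
    """Collapse a comparison's probe-level calls into one transaction.

    A gene enters the basket iff some probe passes |LFC| >= ``lfc_min``
    and adj_p <= ``fdr_max`` (closed thresholds). The representative LFC
    of a multi-probe gene is the passing probe with maximum |LFC|, ties
    broken by input order; the gene-level sign derives from it.
    """
    best: dict[str, DiffExprRecord] = {}
    for rec in comp.records:
        if abs(rec.lfc) >= lfc_min and rec.adj_p <= fdr_max:
            cur = best.get(rec.gene_symbol)
            if cur is None or abs(rec.lfc) > abs(cur.lfc):
                best[rec.gene_symbol] = rec
    return Transaction(
        comparison_id=comp.comparison_id,
        items=frozenset(best),
        sign_of={g: (1 if r.lfc > 0 else -1) for g, r in best.items()},
        lfc_of={g: r.lfc for g, r in best.items()},
    )


def build_transaction_set(
    comparisons: Iterable[Comparison],
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
    drop_empty: bool = True,
) -> TransactionSet:
    """Build transactions for many comparisons, dropping empty baskets.

    Comparisons with no gene passing both thresholds are excluded by
    default (set ``drop_empty=False`` to retain them).
    """
    txs = [build_transaction(c, lfc_min, fdr_max) for c in comparisons]
    if drop_empty:
        txs = [t for t in txs if t.items]
    return TransactionSet(txs)


@dataclass(frozen=True)
class ColumnMap:
    """Column names of a DE table; defaults follow limma's topTable."""

    probe: str = "probe"
    symbol: str = "symbol"
    lfc: str = "logFC"
    adj_p: str = "adj.P.Val"


def read_de_table(
    path: str | Path,
    comparison_id: str | None = None,
    dataset_id: str = "",
    label: str = "",
    columns: ColumnMap = ColumnMap(),
) -> Comparison:
    """Read one tab-separated differential-expression table.

    Rows with a missing symbol or non-finite LFC are skipped. Missing
    mandatory columns raise a :class:`ValueError` naming the column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in (columns.probe, columns.symbol, columns.lfc, columns.adj_p):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        symbol = d[columns.symbol]
        lfc = d[columns.lfc]
        if pd.isna(symbol) or pd.isna(lfc) or not math.isfinite(float(lfc)):
            continue
        records.append(
            DiffExprRecord(
                probe_id=str(d[columns.probe]),
                gene_symbol=str(symbol),
                lfc=float(lfc),
                adj_p=float(d[columns.adj_p]),
            )
        )
    return Comparison(
        comparison_id=comparison_id or path.stem,
        dataset_id=dataset_id,
        label=label,
        records=records,
    )


def read_annotation(path: str | Path) -> AnnotationCatalog:
    """Read an annotation catalog, dispatching on the file extension."""
    p = Path(path)
    if p.suffix.lower() in {".gtf", ".gff"}:
        return AnnotationCatalog.from_gtf(p)
    return AnnotationCatalog.from_tsv(p)


_SIGNED = re.compile(r"^(.*):([+-]1)$")


def write_baskets(
    ts: TransactionSet, path: str | Path, signed: bool = True
) -> None:
    """Serialize to basket format: ``comparison_id<TAB>item1,item2,...``.

    With ``signed=True`` (default) each item is written as ``GENE:+1`` /
    ``GENE:-1`` so that the round trip preserves signs. Items are written
    in lexicographic order.
    """
    with open(path, "w") as fh:
        for t in ts:
            if signed:
                toks = [f"{g}:{t.sign_of[g]:+d}" for g in sorted(t.items)]
            else:
                toks = sorted(t.items)
            fh.write(f"{t.comparison_id}\t{','.join(toks)}\n")


def read_baskets(path: str | Path) -> TransactionSet:
    """Parse a basket file (signed or unsigned dialect, auto-detected).

    Unsigned items are assigned sign +1 and a unit representative LFC.
    Malformed lines raise :class:`BasketParseError` with the line number.
    """
    txs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise BasketParseError(
                    lineno, f"expected 2 tab-separated fields, got {len(parts)}"
                )
            comparison_id, payload = parts
            sign_of: dict[str, int] = {}
            for tok in payload.split(",") if payload else []:
                if not tok:
                    raise BasketParseError(lineno, "empty item token")
                m = _SIGNED.match(tok)
                if m:
                    gene, sign = m.group(1), int(m.group(2))
                else:
                    gene, sign = tok, 1
                if not gene:
                    raise BasketParseError(lineno, f"bad item token {tok!r}")
                sign_of[gene] = sign
            txs.append(
                Transaction(
                    comparison_id=comparison_id,
                    items=frozenset(sign_of),
                    sign_of=sign_of,
                    lfc_of={g: float(s) for g, s in sign_of.items()},
                )
            )
    return TransactionSet(txs)
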