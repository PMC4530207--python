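"""Synthetic differential-expression studies with planted rule structure.

Generates probe-level DE tables whose transaction encoding is known by
construction, so every downstream stage (filtering, transaction
assembly, mining, null simulation, comodulation) can be exercised and
scored against ground truth without any external download.

The generator emulates the structure of a multi-dataset microarray
meta-analysis: a catalog of lncRNA symbols (plus protein-coding decoys
that the biotype filter must remove), a configurable number of
tumour-vs-normal comparisons, *planted patterns* — gene sets that are
differentially expressed together, with fixed signs, in a chosen subset
of carrier comparisons — and independent per-gene Bernoulli background
modulation. Probe-level detail: DE genes get one passing probe with
|LFC| ~ 1 + Exp(mean 1) and adj_p ~ U(0, 0.05); additional probes and
non-DE genes get null probes with LFC ~ Normal(0, 0.3) and adj_p ~
U(0.05, 1), which can never pass the (|LFC| >= 1, adj_p <= 0.05)
thresholds.

Background modulation is independent across genes and comparisons — a
deliberate simplification; real datasets share correlated biology
beyond the planted patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comodulation import PlatformUniverse
from .io_transactions import (
    AnnotationCatalog,
    Comparison,
    DiffExprRecord,
    Transaction,
    TransactionSet,
)

__all__ = [
    "PlantedPattern",
    "SyntheticStudySpec",
    "SyntheticStudy",
    "generate_study",
    "generate_expression_matrix",
    "thirteen_gene_study_spec",
]


@dataclass(frozen=True)
class PlantedPattern:
    """A gene set modulated, with fixed signs, in its carrier comparisons."""

    items: tuple[str, ...]
    carriers: tuple[str, ...]
    signs: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.signs) != len(self.items):
            raise ValueError("signs must align with items")
        if any(s not in (1, -1) for s in self.signs):
            raise ValueError("signs must be +1/-1")


@dataclass
class SyntheticStudySpec:
    """Parameters of one synthetic meta-analysis study.

    Defaults mirror the scale of the real study: 34 comparisons and a
    few-hundred-gene lncRNA universe, with a 5% background chance for
    each measurable gene to be differentially expressed in a comparison.
    """

    n_comparisons: int = 34
    n_items: int = 300
    background_rate: float = 0.05
    planted_patterns: list[PlantedPattern] = field(default_factory=list)
    n_decoys: int = 50  # protein-coding symbols the lncRNA filter must drop
    max_probes_per_gene: int = 3
    universe_dropout: float = 0.0  # per-comparison chance a gene is unmeasurable
    lfc_min: float = 1.0
    fdr_max: float = 0.05
    seed: int = 0

    def item_names(self) -> list[str]:
        return [f"LNC{i:04d}" for i in range(1, self.n_items + 1)]

    def decoy_names(self) -> list[str]:
        return [f"PCG{i:04d}" for i in range(1, self.n_decoys + 1)]

    def comparison_ids(self) -> list[str]:
        return [f"C{i:03d}" for i in range(1, self.n_comparisons + 1)]

    def validate_spec(self) -> None:
        problems = []
        ids = set(self.comparison_ids())
        names = set(self.item_names())
        for k, p in enumerate(self.planted_patterns):
            if not set(p.carriers) <= ids:
                problems.append(f"pattern {k}: carriers outside comparison ids")
            if not set(p.items) <= names:
                problems.append(f"pattern {k}: items outside the universe")
        if not 0 <= self.background_rate <= 1:
            problems.append("background_rate must be in [0, 1]")
        if not 0 <= self.universe_dropout < 1:
            problems.append("universe_dropout must be in [0, 1)")
        if problems:
            raise ValueError("; ".join(problems))


@dataclass
class SyntheticStudy:
    """Generator output: DE tables plus complete ground truth."""

    comparisons: list[Comparison]
    truth: TransactionSet
    universes: PlatformUniverse
    catalog: AnnotationCatalog
    ledger: dict  # per-pattern carrier sets and per-comparison DE items


def generate_study(spec: SyntheticStudySpec) -> SyntheticStudy:
    """Generate probe-level DE tables matching the spec exactly.

    Passing the returned comparisons through the lncRNA filter and
    transaction assembly at (lfc_min, fdr_max) reproduces ``truth``
    item-for-item and sign-for-sign.
    """
    spec.validate_spec()
    rng = np.random.default_rng(spec.seed)
    items = spec.item_names()
    decoys = spec.decoy_names()
    cids = spec.comparison_ids()

    catalog = AnnotationCatalog(
        {**{g: "lincRNA" for g in items}, **{g: "protein_coding" for g in decoys}}
    )

    # planted membership per comparison: gene -> sign
    planted_of: dict[str, dict[str, int]] = {c: {} for c in cids}
    for p in spec.planted_patterns:
        for c in p.carriers:
            for g, s in zip(p.items, p.signs):
                planted_of[c][g] = s

    universes: dict[str, frozenset[str]] = {}
    comparisons: list[Comparison] = []
    truth_txs: list[Transaction] = []
    ledger_items: dict[str, dict[str, int]] = {}

    for c in cids:
        # platform universe: planted genes always measurable
        measurable = set(items)
        if spec.universe_dropout > 0:
            keep = rng.random(len(items)) >= spec.universe_dropout
            measurable = {g for g, k in zip(items, keep) if k}
            measurable |= set(planted_of[c])
        universes[c] = frozenset(measurable)

        de: dict[str, int] = dict(planted_of[c])
        for g in sorted(measurable - set(de)):
            if rng.random() < spec.background_rate:
                de[g] = 1 if rng.random() < 0.5 else -1

        records: list[DiffExprRecord] = []
        lfc_of: dict[str, float] = {}
        probe_no = 0
        for g in sorted(measurable):
            n_probes = int(rng.integers(1, spec.max_probes_per_gene + 1))
            if g in de:
                mag = spec.lfc_min + rng.exponential(1.0)
                lfc = de[g] * mag
                lfc_of[g] = lfc
                probe_no += 1
                records.append(
                    DiffExprRecord(
                        probe_id=f"{c}_p{probe_no:05d}",
                        gene_symbol=g,
                        lfc=float(lfc),
                        adj_p=float(rng.uniform(0.0, spec.fdr_max)),
                    )
                )
                n_probes -= 1
            for _ in range(n_probes):
                probe_no += 1
                records.append(
                    DiffExprRecord(
                        probe_id=f"{c}_p{probe_no:05d}",
                        gene_symbol=g,
                        lfc=float(
                            np.clip(rng.normal(0.0, 0.3), -0.99, 0.99)
                        ),
                        adj_p=float(rng.uniform(spec.fdr_max + 1e-9, 1.0)),
                    )
                )
        # decoy protein-coding records, some of them "passing", to be
        # removed by the biotype filter
        for g in decoys:
            if rng.random() < spec.background_rate:
                probe_no += 1
                records.append(
                    DiffExprRecord(
                        probe_id=f"{c}_p{probe_no:05d}",
                        gene_symbol=g,
                        lfc=float((1 if rng.random() < 0.5 else -1)
                                  * (spec.lfc_min + rng.exponential(1.0))),
                        adj_p=float(rng.uniform(0.0, spec.fdr_max)),
                    )
                )

        comparisons.append(
            Comparison(comparison_id=c, dataset_id="SYNTH", label=c, records=records)
        )
        ledger_items[c] = dict(de)
        if de:
            truth_txs.append(
                Transaction(
                    comparison_id=c,
                    items=frozenset(de),
                    sign_of=dict(de),
                    lfc_of=lfc_of,
                )
            )

    ledger = {
        "patterns": [
            {"items": list(p.items), "carriers": list(p.carriers)}
            for p in spec.planted_patterns
        ],
        "de_items": ledger_items,
    }
    return SyntheticStudy(
        comparisons=comparisons,
        truth=TransactionSet(truth_txs),
        universes=PlatformUniverse(universes),
        catalog=catalog,
        ledger=ledger,
    )


def thirteen_gene_study_spec(
    seed: int = 0,
    background_rate: float = 0.05,
    n_carriers: int = 6,
    pattern_size: int = 13,
) -> SyntheticStudySpec:
    """Study spec mirroring the discovery setting: 34 comparisons, one
    planted 13-gene pattern carried by 6 of them (8 down, 5 up)."""
    spec = SyntheticStudySpec(seed=seed, background_rate=background_rate)
    items = tuple(spec.item_names()[:pattern_size])
    n_down = max(0, pattern_size - 5)
    signs = tuple([-1] * n_down + [1] * (pattern_size - n_down))
    carriers = tuple(spec.comparison_ids()[:n_carriers])
    spec.planted_patterns = [PlantedPattern(items, carriers, signs)]
    return spec


def generate_expression_matrix(
    groups: list[str],
    n_per_group: int | list[int],
    n_probes: int,
    signal_probes: int,
    effect_size: float,
    noise_sd: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gaussian probes x samples matrix with group shifts on signal probes.

    Each group g (index k) shifts the first ``signal_probes`` probes by
    k * ``effect_size``; the rest are pure noise. Returns the matrix and
    a sample -> group label Series, for exercising PCA separation.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    rng = np.random.default_rng(seed)
    if isinstance(n_per_group, int):
        n_per_group = [n_per_group] * len(groups)
    cols, labels, blocks = [], [], []
    for k, (g, n) in enumerate(zip(groups, n_per_group)):
        block = rng.normal(0.0, noise_sd, size=(n_probes, n))
        block[:signal_probes, :] += k * effect_size
        blocks.append(block)
        cols += [f"{g}_{i + 1}" for i in range(n)]
        labels += [g] * n
    m = pd.DataFrame(
        np.concatenate(blocks, axis=1),
        index=[f"probe_{i + 1}" for i in range(n_probes)],
        columns=cols,
    )
    return m, pd.Series(labels, index=cols, name="group")
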