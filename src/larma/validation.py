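"""Sign-consensus signatures and codified cross-dataset validation.

The discovery phase yields a gene signature together with the direction
(up/down in tumour) each gene showed across the discovery comparisons.
Independent evidence — an RNA-seq differential-expression matrix and a
microarray one — then either confirms a gene, supports it in attenuated
form, or fails to validate it.

The published assessment of such evidence is narrative; the three-tier
rule set implemented by :func:`validate` is a codification of it (see
docs/methods.md) and is applied mechanically:

* ``not_validated`` — no evidence at all; or every RNA-seq entry is
  NS/NA; or the finite RNA-seq entries disagree in sign with each other
  or with the discovery consensus.
* ``confirmed`` — in every evidence matrix the gene is assessable in all
  comparisons (no NS/NA), every entry matches the consensus sign, and
  every entry has |LFC| >= ``strong_lfc``.
* ``consistent_attenuated`` — otherwise: signs agree with the consensus
  wherever finite, but the modulation is sub-threshold somewhere or the
  gene could not be assessed in every comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LfcMatrix",
    "ConsensusSignature",
    "ValidationVerdict",
    "consensus_signs",
    "opposite_direction",
    "validate",
]

#: Cell status: finite LFC, not significant, or not assessable.
OK, NS, NA = "ok", "NS", "NA"

_NS_TOKENS = {"ns", "n.s.", "n.s", "NS"}
_NA_TOKENS = {"na", "n.a.", "NA", ""}


class LfcMatrix:
    """Genes x comparisons matrix of log2 fold changes with NS/NA cells.

    ``values`` holds floats (NaN where not finite); ``status`` records
    whether each cell is a finite LFC ("ok"), a measured-but-not-
    significant call ("NS"), or not assessable ("NA").
    """

    def __init__(self, values: pd.DataFrame, status: pd.DataFrame | None = None):
        if values.index.has_duplicates or values.columns.has_duplicates:
            raise ValueError("gene and comparison labels must be unique")
        self.values = values.astype(float)
        if status is None:
            status = pd.DataFrame(
                np.where(np.isfinite(self.values.to_numpy()), OK, NA),
                index=values.index,
                columns=values.columns,
            )
        self.status = status

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def comparisons(self) -> pd.Index:
        return self.values.columns

    def finite(self, gene: str, comparisons: Sequence[str] | None = None) -> pd.Series:
        """Finite LFC entries of a gene over the given (or all) columns."""
        row = self.values.loc[gene]
        if comparisons is not None:
            row = row[list(comparisons)]
        return row.dropna()

    @classmethod
    def from_tsv(cls, path: str | Path, index_col: int = 0) -> "LfcMatrix":
        raw = pd.read_csv(path, sep="\t", index_col=index_col, dtype=str)
        values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
        status = pd.DataFrame(NA, index=raw.index, columns=raw.columns)
        for g in raw.index:
            for c in raw.columns:
                tok = raw.at[g, c]
                tok = "" if pd.isna(tok) else str(tok).strip()
                if tok in _NS_TOKENS or tok.lower() in _NS_TOKENS:
                    values.at[g, c], status.at[g, c] = np.nan, NS
                elif tok in _NA_TOKENS or tok.lower() in _NA_TOKENS:
                    values.at[g, c], status.at[g, c] = np.nan, NA
                else:
                    values.at[g, c], status.at[g, c] = float(tok), OK
        return cls(values, status)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy().astype(object)
        arr = self.status.to_numpy()
        for i, g in enumerate(out.index):
            for j, c in enumerate(out.columns):
                if arr[i, j] == NS:
                    out.iat[i, j] = "NS"
                elif arr[i, j] == NA:
                    out.iat[i, j] = "NA"
        out.to_csv(path, sep="\t", index_label="gene")


Consensus = Literal[1, -1, "discordant", "NA"]


@dataclass
class ConsensusSignature:
    """Per-gene discovery-direction consensus over source comparisons."""

    consensus: dict[str, Consensus]
    source_comparisons: tuple[str, ...]

    @property
    def genes(self) -> list[str]:
        return list(self.consensus)

    def count(self, value: Consensus) -> int:
        return sum(1 for v in self.consensus.values() if v == value)


@dataclass(frozen=True)
class ValidationVerdict:
    gene: str
    status: Literal["confirmed", "consistent_attenuated", "not_validated"]
    reason: str

    @property
    def validated(self) -> bool:
        return self.status != "not_validated"


def consensus_signs(
    m: LfcMatrix, comparisons: Sequence[str] | None = None
) -> ConsensusSignature:
    """Per-gene sign consensus across the selected discovery comparisons.

    A gene gets +1 (-1) when all its finite entries are positive
    (negative), "discordant" on mixed signs, and "NA" when no entry is
    finite. Unknown comparison ids raise.
    """
    cols = list(m.comparisons) if comparisons is None else list(comparisons)
    unknown = set(cols) - set(m.comparisons)
    if unknown:
        raise KeyError(f"unknown comparison ids: {sorted(unknown)}")
    out: dict[str, Consensus] = {}
    for g in m.genes:
        vals = m.finite(g, cols)
        if vals.empty:
            out[g] = "NA"
        elif (vals > 0).all():
            out[g] = 1
        elif (vals < 0).all():
            out[g] = -1
        else:
            out[g] = "discordant"
    return ConsensusSignature(consensus=out, source_comparisons=tuple(cols))


def opposite_direction(
    sig: ConsensusSignature, m: LfcMatrix, comparison: str
) -> set[str]:
    """Genes whose finite LFC in ``comparison`` opposes a +/-1 consensus."""
    if comparison not in m.comparisons:
        raise KeyError(f"unknown comparison id: {comparison}")
    out: set[str] = set()
    for g, cons in sig.consensus.items():
        if cons not in (1, -1) or g not in m.genes:
            continue
        v = m.values.at[g, comparison]
        if np.isfinite(v) and np.sign(v) == -cons:
            out.add(g)
    return out


def _gene_entries(m: LfcMatrix, gene: str) -> tuple[np.ndarray, np.ndarray]:
    """(values, status) arrays for a gene; empty when absent."""
    if gene not in m.genes:
        return np.array([]), np.array([])
    return m.values.loc[gene].to_numpy(), m.status.loc[gene].to_numpy()


def validate(
    sig: ConsensusSignature,
    rnaseq: LfcMatrix,
    evidence: Iterable[LfcMatrix] = (),
    strong_lfc: float = 1.0,
) -> list[ValidationVerdict]:
    """Issue a codified verdict per signature gene.

    ``rnaseq`` is the designated RNA-seq evidence matrix (arbiter of
    non-validation); ``evidence`` lists any further matrices (e.g. an
    independent microarray study). See the module docstring for the
    three-tier rules. Verdicts are invariant to column order.
    """
    matrices = [rnaseq, *evidence]
    verdicts: list[ValidationVerdict] = []
    for g, cons in sig.consensus.items():
        if cons not in (1, -1):
            verdicts.append(
                ValidationVerdict(g, "not_validated", f"consensus is {cons}")
            )
            continue
        if all(g not in m.genes for m in matrices):
            verdicts.append(ValidationVerdict(g, "not_validated", "no evidence"))
            continue

        rs_vals, _ = _gene_entries(rnaseq, g)
        rs_finite = rs_vals[np.isfinite(rs_vals)]
        if rs_finite.size == 0:
            verdicts.append(
                ValidationVerdict(
                    g, "not_validated", "not significantly modulated in RNA-seq"
                )
            )
            continue
        signs = np.sign(rs_finite)
        if len(set(signs)) > 1:
            verdicts.append(
                ValidationVerdict(g, "not_validated", "discordant RNA-seq signs")
            )
            continue
        if signs[0] != cons:
            verdicts.append(
                ValidationVerdict(
                    g, "not_validated", "RNA-seq sign opposes discovery consensus"
                )
            )
            continue

        confirmed = True
        reasons = []
        for m in matrices:
            vals, _ = _gene_entries(m, g)
            finite = vals[np.isfinite(vals)]
            if finite.size < vals.size or finite.size == 0:
                confirmed = False
                reasons.append("not assessable in every comparison")
                continue
            if not (np.sign(finite) == cons).all():
                confirmed = False
                reasons.append("sign-discordant evidence")
                continue
            if not (np.abs(finite) >= strong_lfc).all():
                confirmed = False
                reasons.append("attenuated modulation")
        if confirmed:
            verdicts.append(
                ValidationVerdict(
                    g, "confirmed", "consistent strong modulation in all evidence"
                )
            )
        else:
            verdicts.append(
                ValidationVerdict(
                    g, "consistent_attenuated", "; ".join(sorted(set(reasons)))
                )
            )
    return verdicts
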