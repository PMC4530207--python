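"""Packaged fixture matrices for the 13-lncRNA brain-tumour signature.

Three small LFC matrices transcribed from the published meta-analysis
are shipped with the package:

* discovery — 13 lncRNAs x 6 comparisons: five brain-tumour grades vs
  normal brain from GEO dataset GDS1962 plus one ovarian-cancer
  comparison from GDS3592;
* validation microarray — the same genes in five brain-tumour
  comparisons of the independent E-GEOD-16011 ArrayExpress study;
* validation RNA-seq — the same genes in three tumour types of the
  SRP027383 RNA-seq study ("n.s." marks non-significant calls).
"""

from __future__ import annotations

from importlib import resources

from .io_transactions import Comparison, DiffExprRecord, TransactionSet, build_transaction_set
from .validation import LfcMatrix

__all__ = [
    "SIGNATURE_GENES",
    "GDS1962_COMPARISONS",
    "GDS3592_COMPARISON",
    "load_discovery_lfc",
    "load_validation_microarray",
    "load_validation_rnaseq",
    "discovery_transactions",
]

#: The 13 signature lncRNAs, in the published row order.
SIGNATURE_GENES = (
    "OIP5-AS1",
    "RFPL1S",
    "MEG3",
    "KRTAP5-AS1",
    "LINC00301",
    "PART1",
    "PPP1R26-AS1",
    "SYN2",
    "CRNDE",
    "RUSC1-AS1",
    "UBL7-AS1",
    "DLEU2",
    "UHRF1",
)

GDS1962_COMPARISONS = (
    "GDS1962:astrocytoma_gII",
    "GDS1962:astrocytoma_gIII",
    "GDS1962:glioblastoma_gIV",
    "GDS1962:oligodendroglioma_gII",
    "GDS1962:oligodendroglioma_gIII",
)

GDS3592_COMPARISON = "GDS3592:ovarian_cancer"


def _load(name: str) -> LfcMatrix:
    with resources.as_file(
        resources.files("larma.data").joinpath(name)
    ) as path:
        return LfcMatrix.from_tsv(path)


def load_discovery_lfc() -> LfcMatrix:
    """13 genes x 6 discovery comparisons (GDS1962 + GDS3592)."""
    return _load("discovery_lfc.tsv")


def load_validation_microarray() -> LfcMatrix:
    """13 genes x 5 E-GEOD-16011 brain-tumour comparisons."""
    return _load("validation_microarray_lfc.tsv")


def load_validation_rnaseq() -> LfcMatrix:
    """13 genes x 3 SRP027383 RNA-seq tumour comparisons."""
    return _load("validation_rnaseq_lfc.tsv")


def discovery_transactions(
    lfc_min: float = 1.0, fdr_max: float = 0.05
) -> TransactionSet:
    """Encode each discovery comparison column as a transaction.

    Genes enter a comparison's basket when |LFC| >= ``lfc_min`` (the
    printed discovery values are all significant calls, so each is given
    a nominal adjusted p of 0.01).
    """
    m = load_discovery_lfc()
    comparisons = []
    for c in m.comparisons:
        col = m.values[c].dropna()
        records = [
            DiffExprRecord(probe_id=f"{c}:{g}", gene_symbol=g, lfc=float(v), adj_p=0.01)
            for g, v in col.items()
        ]
        comparisons.append(
            Comparison(
                comparison_id=c, dataset_id=c.split(":")[0], label=c, records=records
            )
        )
    return build_transaction_set(comparisons, lfc_min=lfc_min, fdr_max=fdr_max)
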