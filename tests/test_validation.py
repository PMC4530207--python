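import numpy as np
import pandas as pd
import pytest

from larma.datasets import (
    GDS1962_COMPARISONS,
    GDS3592_COMPARISON,
    SIGNATURE_GENES,
)
from larma.validation import (
    LfcMatrix,
    consensus_signs,
    opposite_direction,
    validate,
)


def matrix(data: dict[str, list], genes: list[str]) -> LfcMatrix:
    """LfcMatrix from column dict; None -> NA, 'ns' -> NS."""
    values = pd.DataFrame(index=genes, columns=list(data), dtype=float)
    status = pd.DataFrame("NA", index=genes, columns=list(data))
    for c, col in data.items():
        for g, v in zip(genes, col):
            if v is None:
                continue
            if v == "ns":
                status.at[g, c] = "NS"
            else:
                values.at[g, c] = float(v)
                status.at[g, c] = "ok"
    return LfcMatrix(values, status)


class TestConsensusSigns:
    def test_discovery_brain_block_eight_down_five_up(self, discovery_lfc):
        sig = consensus_signs(discovery_lfc, GDS1962_COMPARISONS)
        assert sig.count(-1) == 8
        assert sig.count(1) == 5
        down = {g for g, v in sig.consensus.items() if v == -1}
        assert down == {
            "OIP5-AS1", "RFPL1S", "MEG3", "KRTAP5-AS1", "LINC00301",
            "PART1", "PPP1R26-AS1", "SYN2",
        }

    def test_single_column_consensus_is_entry_sign(self, discovery_lfc):
        sig = consensus_signs(discovery_lfc, [GDS3592_COMPARISON])
        for g in discovery_lfc.genes:
            v = discovery_lfc.values.at[g, GDS3592_COMPARISON]
            assert sig.consensus[g] == np.sign(v)

    def test_mixed_signs_discordant(self):
        m = matrix({"c1": [1.2], "c2": [-0.8]}, ["G"])
        assert consensus_signs(m).consensus["G"] == "discordant"

    def test_no_finite_entries_reported_na(self):
        m = matrix({"c1": ["ns"], "c2": [None]}, ["G"])
        assert consensus_signs(m).consensus["G"] == "NA"

    def test_unknown_comparison_raises(self, discovery_lfc):
        with pytest.raises(KeyError):
            consensus_signs(discovery_lfc, ["nope"])


class TestOppositeDirection:
    def test_ovarian_column_has_seven_reversals(self, discovery_lfc):
        sig = consensus_signs(discovery_lfc, GDS1962_COMPARISONS)
        opp = opposite_direction(sig, discovery_lfc, GDS3592_COMPARISON)
        assert opp == {
            "MEG3", "KRTAP5-AS1", "LINC00301", "PART1",
            "PPP1R26-AS1", "SYN2", "CRNDE",
        }

    def test_ovarian_column_majority_upregulated(self, discovery_lfc):
        col = discovery_lfc.values[GDS3592_COMPARISON]
        assert int((col > 0).sum()) == 10

    def test_consensus_column_yields_empty_set(self, discovery_lfc):
        sig = consensus_signs(discovery_lfc, GDS1962_COMPARISONS)
        assert opposite_direction(sig, discovery_lfc, GDS1962_COMPARISONS[0]) == set()

    def test_all_ns_column_yields_empty_set(self):
        m = matrix({"c1": [1.0, -1.0], "c2": ["ns", "ns"]}, ["A", "B"])
        sig = consensus_signs(m, ["c1"])
        assert opposite_direction(sig, m, "c2") == set()


@pytest.fixture(scope="module")
def verdicts(discovery_lfc, validation_rnaseq, validation_microarray):
    sig = consensus_signs(discovery_lfc, GDS1962_COMPARISONS)
    return {
        v.gene: v
        for v in validate(sig, validation_rnaseq, [validation_microarray])
    }


class TestValidate:
    def test_three_genes_not_validated(self, verdicts):
        not_val = {g for g, v in verdicts.items() if v.status == "not_validated"}
        assert not_val == {"LINC00301", "PPP1R26-AS1", "MEG3"}

    def test_six_confirmed(self, verdicts):
        confirmed = {g for g, v in verdicts.items() if v.status == "confirmed"}
        assert confirmed == {"RFPL1S", "KRTAP5-AS1", "PART1", "SYN2", "DLEU2", "UHRF1"}

    def test_attenuated_genes(self, verdicts):
        att = {g for g, v in verdicts.items() if v.status == "consistent_attenuated"}
        assert att == {"OIP5-AS1", "UBL7-AS1", "CRNDE", "RUSC1-AS1"}

    def test_statuses_partition_signature(self, verdicts):
        assert set(verdicts) == set(SIGNATURE_GENES)
        assert sum(v.validated for v in verdicts.values()) == 10

    def test_evidence_identical_to_discovery_all_confirmed(self, discovery_lfc):
        sig = consensus_signs(discovery_lfc, GDS1962_COMPARISONS)
        brain = LfcMatrix(discovery_lfc.values[list(GDS1962_COMPARISONS)])
        verdicts = validate(sig, brain)
        assert all(v.status == "confirmed" for v in verdicts)

    def test_ns_in_one_rnaseq_comparison_attenuates(self):
        genes = ["G"]
        sig = consensus_signs(matrix({"d1": [2.0], "d2": [1.5]}, genes))
        rnaseq = matrix({"r1": [1.4], "r2": ["ns"], "r3": [2.0]}, genes)
        (v,) = validate(sig, rnaseq)
        assert v.status == "consistent_attenuated"

    def test_column_order_invariance(
        self, discovery_lfc, validation_rnaseq, validation_microarray
    ):
        sig = consensus_signs(discovery_lfc, GDS1962_COMPARISONS)
        shuffled = LfcMatrix(
            validation_rnaseq.values.iloc[:, ::-1],
            validation_rnaseq.status.iloc[:, ::-1],
        )
        a = validate(sig, validation_rnaseq, [validation_microarray])
        b = validate(sig, shuffled, [validation_microarray])
        assert [(v.gene, v.status) for v in a] == [(v.gene, v.status) for v in b]

    def test_gene_absent_everywhere_is_no_evidence(self):
        sig = consensus_signs(matrix({"d": [1.0]}, ["G"]))
        rnaseq = matrix({"r": [1.0]}, ["OTHER"])
        (v,) = validate(sig, rnaseq)
        assert v.status == "not_validated" and v.reason == "no evidence"
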