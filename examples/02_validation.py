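"""Consensus directions and cross-dataset validation of the signature.

Computes the per-gene up/down consensus over the five brain-tumour
discovery comparisons, checks which genes reverse direction in the
ovarian comparison, then issues codified verdicts against the
independent microarray and RNA-seq evidence matrices.
"""

from larma import datasets
from larma.validation import consensus_signs, opposite_direction, validate

m = datasets.load_discovery_lfc()
sig = consensus_signs(m, datasets.GDS1962_COMPARISONS)
print(f"consensus over brain comparisons: {sig.count(-1)} down, {sig.count(1)} up")

opp = opposite_direction(sig, m, datasets.GDS3592_COMPARISON)
print(f"{len(opp)} genes reversed in the ovarian comparison: {sorted(opp)}")

verdicts = validate(
    sig,
    datasets.load_validation_rnaseq(),
    [datasets.load_validation_microarray()],
    strong_lfc=1.0,
)
for v in verdicts:
    print(f"  {v.gene:<12} {v.status:<22} {v.reason}")
n_ok = sum(v.validated for v in verdicts)
print(f"validated (confirmed or attenuated): {n_ok}/{len(verdicts)}")
# A gene fails validation only when RNA-seq gives no significant call or
# contradicts the discovery direction; attenuated genes agree in sign but
# miss the |LFC| >= 1 bar or an assessable call somewhere.
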