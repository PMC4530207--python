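"""PCA separation of tumour and normal samples.

Simulates a log2 intensity matrix with a group shift on a probe subset,
runs centred unscaled PCA on all probes and on the signal probes alone,
and scores the group separation with the mean silhouette on PC1/PC2.
"""

from larma.pca import run_pca, separation_score
from larma.synth import generate_expression_matrix

m, labels = generate_expression_matrix(
    groups=["normal", "tumor"], n_per_group=25, n_probes=200,
    signal_probes=10, effect_size=4.0, noise_sd=1.0, seed=0,
)

for name, subset in [("all probes", None), ("signal probes", list(m.index[:10]))]:
    p = run_pca(m, probe_subset=subset)
    sil = separation_score(p, labels, k_components=2)
    print(f"{name:>13}: PC1 variance fraction "
          f"{p.explained_variance_ratio[0]:.2f}, silhouette {sil:.2f}")
# The ten signal probes carry all the group structure: restricting the
# PCA to them concentrates the variance on PC1 and sharpens the
# silhouette, mirroring how a small signature can separate tissue types.
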