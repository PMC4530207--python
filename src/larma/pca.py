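"""PCA of log2 intensity matrices and cluster-separation scoring.

Samples are the observations and probes the variables, matching the
convention of treating array samples as "individuals". Centering is on
and scaling off by default: the analysis runs on log2 normalized
intensities as-is, so high-variance probes dominate, which is the
intended behaviour for expression matrices. PCA may be restricted to a
probe subset (e.g. the probes of a mined lncRNA signature).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

__all__ = ["PcaResult", "run_pca", "separation_score", "load_matrix"]


@dataclass
class PcaResult:
    """SVD-based PCA output.

    scores : samples x components DataFrame
    loadings : probes x components DataFrame (orthonormal columns)
    explained_variance_ratio : fraction of variance per component
    mean : per-probe column means removed before the SVD
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    mean: pd.Series

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self) -> pd.DataFrame:
        """scores . loadings^T + mean; exact when all components kept."""
        x = self.scores.to_numpy() @ self.loadings.to_numpy().T
        return pd.DataFrame(
            x + self.mean.to_numpy(),
            index=self.scores.index,
            columns=self.loadings.index,
        )


def run_pca(
    m: pd.DataFrame,
    probe_subset: Sequence[str] | None = None,
    center: bool = True,
    scale: bool = False,
    n_components: int | None = None,
) -> PcaResult:
    """Exact SVD-based PCA of a probes x samples expression matrix.

    ``m`` has probe rows and sample columns; internally samples are the
    observations. Probe rows with missing values are dropped. The sign
    of each component is fixed so its largest-magnitude loading is
    positive, making score files reproducible.
    """
    if probe_subset is not None:
        subset = [p for p in probe_subset if p in m.index]
        if not subset:
            raise ValueError("probe subset is disjoint from the matrix rows")
        m = m.loc[subset]
    m = m.dropna(axis=0)
    x = m.to_numpy(dtype=float).T  # samples x probes
    n_samples, n_probes = x.shape
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")

    mean = x.mean(axis=0) if center else np.zeros(n_probes)
    xc = x - mean
    if scale:
        sd = xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xc = xc / sd

    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # fix component signs: largest-magnitude loading positive
    for j in range(vt.shape[0]):
        k = np.argmax(np.abs(vt[j]))
        if vt[j, k] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0

    var = s**2 / (n_samples - 1)
    total = xc.var(axis=0, ddof=1).sum()
    ratio = var / total if total > 0 else np.zeros_like(var)

    k = len(s) if n_components is None else min(n_components, len(s))
    comps = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(
            (u[:, :k] * s[:k]), index=m.columns, columns=comps
        ),
        loadings=pd.DataFrame(vt[:k].T, index=m.index, columns=comps),
        explained_variance_ratio=ratio[:k],
        # with scale=True reconstruct() returns the scaled matrix + mean 0
        mean=pd.Series(np.zeros(n_probes) if scale else mean, index=m.index),
    )


def separation_score(
    p: PcaResult, labels: Sequence[str] | pd.Series, k_components: int = 2
) -> float:
    """Mean silhouette of the samples in the first-k score space.

    Quantifies how cleanly the labelled groups (e.g. tumour vs normal)
    separate on the leading principal components; in [-1, 1]. Samples in
    singleton classes contribute a silhouette of 0.
    """
    labels = np.asarray(labels)
    if len(labels) != p.scores.shape[0]:
        raise ValueError("labels length must match the number of samples")
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least 2 label classes")
    x = p.scores.iloc[:, : min(k_components, p.n_components)].to_numpy()
    return float(silhouette_samples(x, labels).mean())


def load_matrix(path: str) -> pd.DataFrame:
    """Read a probes x samples TSV (probe ids in the first column)."""
    return pd.read_csv(path, sep="\t", index_col=0)
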