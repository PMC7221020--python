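"""PCA stratification of the binary mutation matrix.

Covariance PCA on the column-centered 0/1 matrix (centered, deliberately
*not* variance-scaled: the columns already share the 0/1 scale, and scaling
would inflate rarely mutated genes).  The genes with the largest absolute
loadings on the first components are the candidate stratifiers; a mean
silhouette over the sample groups induced by a gene pair's joint mutation
status quantifies how sharply that pair partitions the cohort in PC space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .errors import DegenerateInputError, PanelError
from .matrix import MutationMatrix


@dataclass
class PcaResult:
    loadings: pd.DataFrame  # genes x components, unit-norm columns
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame  # samples x components


def run_pca(m: MutationMatrix, n_components: int = 2) -> PcaResult:
    """Covariance-based PCA with a deterministic sign convention.

    Each loading column is flipped so that its largest-magnitude entry is
    positive, making outputs bit-stable across runs and platforms.
    """
    X = m.df.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise DegenerateInputError("PCA needs at least 2 samples")
    if (X.var(axis=0) > 0).sum() < 2:
        raise DegenerateInputError("PCA needs >=2 genes with nonzero variance")
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    load = pca.components_.T  # genes x comps
    for k in range(load.shape[1]):
        j = int(np.argmax(np.abs(load[:, k])))
        if load[j, k] < 0:
            load[:, k] = -load[:, k]
            scores[:, k] = -scores[:, k]
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PcaResult(
        loadings=pd.DataFrame(load, index=m.genes, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        scores=pd.DataFrame(scores, index=m.samples, columns=comp_names),
    )


def rank_stratifiers(p: PcaResult, k: int = 2) -> list[str]:
    """Genes ranked by max |loading| over the first ``k`` components.

    Ties are broken by panel (input column) order, which is stable.
    """
    if p.loadings.shape[1] < k:
        raise ValueError(f"PCA result has {p.loadings.shape[1]} components, need {k}")
    key = p.loadings.iloc[:, :k].abs().max(axis=1)
    order = np.argsort(-key.to_numpy(), kind="stable")
    return [p.loadings.index[i] for i in order]


def separation_score(
    m: MutationMatrix, gene_pair: tuple[str, str], p: PcaResult
) -> float:
    """Mean silhouette of the <=4 joint-status groups of a gene pair in
    PC1-PC2 score space (Euclidean distance).  Higher = sharper separation."""
    ga, gb = gene_pair
    for g in (ga, gb):
        if g not in m.df.columns:
            raise PanelError(f"{g!r} not in matrix")
    labels = (2 * m.df[ga] + m.df[gb]).to_numpy()
    if len(np.unique(labels)) < 2:
        raise DegenerateInputError(
            f"joint status of {ga}/{gb} induces fewer than 2 groups"
        )
    X = p.scores.iloc[:, :2].to_numpy()
    if np.allclose(X, X[0]):
        return 0.0
    return float(silhouette_score(X, labels, metric="euclidean"))


def scatter_export(m: MutationMatrix, p: PcaResult) -> pd.DataFrame:
    """Long-format table (sample, PC1, PC2, per-gene status) for plotting."""
    out = p.scores.iloc[:, :2].copy()
    for g in m.genes:
        out[g] = m.df[g].to_numpy()
    return out
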