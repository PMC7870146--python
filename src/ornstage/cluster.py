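"""Feature selection, dimensionality reduction, and density clustering.

Clustering follows the published recipe: PCA on a curated feature set (DE
genes from the most diverse stage plus known sensory receptors), an optional
2-D embedding (UMAP or t-SNE) for visualization, and HDBSCAN with
min_cluster_size=6, min_samples=4.  The clusterer is a pluggable stage —
any backend that yields per-cell labels can stand in — and by default it
operates on principal-component scores, not the 2-D embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA

from .params import AnalysisParams, DEFAULT_PARAMS
from .qc import _dense

__all__ = [
    "select_overdispersed_genes",
    "EmbeddingResult",
    "reduce_and_embed",
    "ClusterAssignment",
    "density_cluster",
]


def select_overdispersed_genes(
    adata: AnnData, n: int = 500, n_bins: int = 20
) -> list[str]:
    """Top-n genes by binned normalized dispersion.

    Dispersion = variance/mean per gene; genes are grouped into equal-count
    mean-expression bins and dispersions z-scored within each bin so highly
    expressed genes do not dominate.  Deterministic: ties break
    lexicographically on the gene identifier.
    """
    values = _dense(adata.X).astype(float)
    means = values.mean(axis=0)
    var = values.var(axis=0)
    nonzero = var > 0
    if nonzero.sum() <= n:
        if nonzero.sum() < n:
            import warnings

            warnings.warn(
                f"only {int(nonzero.sum())} genes with nonzero variance; "
                "returning all of them"
            )
        return sorted(adata.var_names[nonzero])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(means > 0, var / means, 0.0)
    df = pd.DataFrame(
        {"gene": adata.var_names, "mean": means, "disp": disp}
    )[nonzero]
    df["bin"] = pd.qcut(df["mean"].rank(method="first"), q=n_bins, labels=False)
    def _z(s: pd.Series) -> pd.Series:
        sd = s.std(ddof=0)
        return (s - s.mean()) / sd if sd > 0 else s * 0.0
    df["z"] = df.groupby("bin")["disp"].transform(_z)
    df = df.sort_values(["z", "gene"], ascending=[False, True], kind="mergesort")
    return df["gene"].head(n).tolist()


@dataclass
class EmbeddingResult:
    pcs: np.ndarray
    coords: np.ndarray
    explained_variance: np.ndarray
    method: str
    features: list[str]
    seed: int


def reduce_and_embed(
    adata: AnnData,
    features: list[str],
    n_pcs: int = 20,
    method: str = "none",
    seed: int = 0,
) -> EmbeddingResult:
    """PCA on the feature submatrix, then an optional 2-D embedding.

    ``method`` is "umap", "tsne", or "none" (coords = first two PCs).
    Deterministic under a fixed seed.
    """
    missing = [g for g in features if g not in adata.var_names]
    if missing:
        raise ValueError(f"features absent from matrix: {missing[:5]}...")
    sub = _dense(adata[:, features].X).astype(float)
    if np.allclose(sub.std(axis=0), 0):
        raise ValueError("feature submatrix is constant; nothing to reduce")
    n_pcs = min(n_pcs, min(sub.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    pcs = pca.fit_transform(sub)
    if method == "none":
        coords = pcs[:, :2].copy()
    elif method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(2.0, (adata.n_obs - 1) / 3.0))
        coords = TSNE(
            n_components=2, random_state=seed, perplexity=perplexity, init="pca"
        ).fit_transform(pcs)
    elif method == "umap":
        import umap  # deferred: heavy import

        coords = umap.UMAP(n_components=2, random_state=seed).fit_transform(pcs)
    else:
        raise ValueError(f"unknown embedding method: {method!r}")
    return EmbeddingResult(
        pcs=pcs,
        coords=np.asarray(coords, dtype=float),
        explained_variance=pca.explained_variance_,
        method=method,
        features=list(features),
        seed=seed,
    )


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels; -1 marks unassigned (noise) cells."""

    labels: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))

    def as_series(self, index) -> pd.Series:
        return pd.Series(self.labels, index=index, name="cluster")


def _contiguous(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 in order of first appearance; noise stays -1."""
    out = np.full(labels.shape, -1, dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab < 0:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def density_cluster(
    representation: np.ndarray,
    min_cluster_size: int | None = None,
    min_samples: int | None = None,
    params: AnalysisParams = DEFAULT_PARAMS,
) -> ClusterAssignment:
    """HDBSCAN over a representation (PC scores by default upstream).

    Cells the density clusterer cannot associate with any cluster are
    unassigned (-1), mirroring the handful of cells per time point dropped
    from the published embeddings.
    """
    mcs = params.hdbscan_min_cluster_size if min_cluster_size is None else min_cluster_size
    ms = params.hdbscan_min_samples if min_samples is None else min_samples
    X = np.asarray(representation, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("representation contains non-finite values")
    if X.shape[0] < mcs:
        labels = np.full(X.shape[0], -1, dtype=int)
    else:
        model = HDBSCAN(min_cluster_size=mcs, min_samples=ms, copy=True)
        labels = _contiguous(model.fit_predict(X))
    return ClusterAssignment(
        labels=labels,
        method="hdbscan",
        params={"min_cluster_size": mcs, "min_samples": ms},
    )
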