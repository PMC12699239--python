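"""Unsupervised structure views of the candidate-assay expression matrix.

Principal component analysis and agglomerative hierarchical clustering of
the samples, computed on the significant-assay slice of the expression
matrix.  Columns are z-scored by default (the heatmap convention) so that
every assay contributes on the same scale; rows with missing entries are
row-mean imputed before either view.  Stochastic neighbour embeddings
(t-SNE, UMAP) are deliberately not provided here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

__all__ = ["EmbeddingResult", "Dendrogram", "pca_embed", "hierarchical_cluster"]


@dataclass
class EmbeddingResult:
    """Sample coordinates in PCA space plus explained-variance fractions."""

    sample_ids: list[str]
    coordinates: np.ndarray  # (n_samples, n_components)
    explained_variance_fractions: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over samples.

    ``linkage_matrix`` is in scipy's standard (n-1, 4) encoding; leaf order
    is deterministic given the input row order.
    """

    labels: list[str]
    linkage_matrix: np.ndarray
    metric: str
    linkage: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels for a cut into ``n_clusters`` groups."""
        return hierarchy.fcluster(self.linkage_matrix, n_clusters,
                                  criterion="maxclust")

    def to_newick(self) -> str:
        """Serialize the merge tree as a Newick string with branch lengths."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return walk(tree, tree.dist) + ";"


def _prepare(matrix: pd.DataFrame | np.ndarray, scale: bool) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        labels = [str(i) for i in matrix.index]
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in range(X.shape[0])]
    # Row-mean imputation of missing cells, then optional per-column z-score.
    if np.isnan(X).any():
        row_means = np.nanmean(X, axis=1, keepdims=True)
        X = np.where(np.isnan(X), row_means, X)
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return X, labels


def pca_embed(
    matrix: pd.DataFrame | np.ndarray,
    n_components: int | None = None,
    scale: bool = True,
) -> EmbeddingResult:
    """Project samples onto the leading principal components.

    Columns are centred (and z-scaled when ``scale``); coordinates are the
    projections onto the leading eigenvectors of the covariance matrix.
    Raises on an all-constant matrix, for which no direction of variance
    exists.
    """
    X, labels = _prepare(matrix, scale)
    n, p = X.shape
    max_comp = min(n - 1, p)
    if max_comp < 1:
        raise ValueError("PCA needs at least two samples and one assay")
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(f"n_components must be <= {max_comp}")
    if np.allclose(X - X.mean(axis=0), 0):
        raise ValueError("matrix has zero variance; PCA undefined")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    return EmbeddingResult(labels, coords, pca.explained_variance_ratio_)


def hierarchical_cluster(
    matrix: pd.DataFrame | np.ndarray,
    metric: str = "euclidean",
    linkage: str = "average",
    scale: bool = True,
) -> Dendrogram:
    """Agglomerative clustering of samples (rows).

    Supported metrics: ``euclidean``, ``correlation``; linkages:
    ``average``, ``complete``, ``ward`` (ward requires euclidean distance).
    """
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported metric {metric!r}")
    if linkage not in ("average", "complete", "ward"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if linkage == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")
    X, labels = _prepare(matrix, scale)
    if X.shape[0] < 2:
        raise ValueError("clustering needs at least two samples")
    dist = pdist(X, metric=metric)
    if np.isnan(dist).any():
        sq = squareform(dist)
        i, j = map(int, np.argwhere(np.isnan(sq))[0])
        raise ValueError(
            f"distance between samples {labels[i]!r} and {labels[j]!r} is NaN "
            f"(constant rows under the correlation metric?)")
    Z = hierarchy.linkage(dist, method=linkage)
    return Dendrogram(labels, Z, metric, linkage)
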