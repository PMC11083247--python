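"""Unsupervised structure discovery on the TIS matrix: HCA and PCA.

Hierarchical clustering treats each sample's normalized fingerprint as a
point in 501-dimensional space (Euclidean metric). The linkage method is
chosen by comparing agglomerative coefficients; Ward linkage (implemented
in the squared-distance, Ward.D2 sense via SciPy) typically wins on
fingerprint data with planted group structure.

PCA is run on mean-centered data without unit-variance scaling: the
channels are already on a common base-peak-normalized scale, and scaling
would inflate noise-only channels. A ``scale`` flag is exposed for the
alternative convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .tis import TisMatrix

__all__ = [
    "HcaResult",
    "PcaResult",
    "agglomerative_coefficient",
    "select_linkage",
    "run_hca",
    "run_pca",
    "to_newick",
]

LINKAGE_METHODS = ("average", "single", "complete", "ward")


def _observations(matrix: TisMatrix) -> np.ndarray:
    X = matrix.X
    if not np.all(np.isfinite(X)):
        raise ValueError("TIS matrix contains non-finite values")
    return X


@dataclass
class HcaResult:
    linkage_method: str
    merges: np.ndarray  # SciPy linkage matrix, (n-1) x 4
    labels: list[str]
    agglomerative_coefficient: float

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels from cutting the tree at ``n_clusters``."""
        return hierarchy.fcluster(self.merges, n_clusters, criterion="maxclust")

    def merges_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["left", "right", "height", "size"]
        )

    def newick(self) -> str:
        return to_newick(self.merges, self.labels)


def _first_merge_heights(Z: np.ndarray, n: int) -> np.ndarray:
    """Height at which each original observation is first merged."""
    heights = np.empty(n)
    seen = np.zeros(n, dtype=bool)
    members: list[list[int]] = [[i] for i in range(n)]
    for k in range(Z.shape[0]):
        a, b, h = int(Z[k, 0]), int(Z[k, 1]), Z[k, 2]
        merged = members[a] + members[b]
        for leaf in merged:
            if not seen[leaf]:
                heights[leaf] = h
                seen[leaf] = True
        members.append(merged)
    return heights


def agglomerative_coefficient(matrix: TisMatrix, method: str = "ward") -> float:
    """Strength of clustering structure, mean over samples of 1 - d_first/d_last.

    ``d_first`` is the height at which a sample first merges into a cluster
    and ``d_last`` the height of the final merge (the agnes definition).
    Values near 1 indicate tight, well-separated clusters.
    """
    X = _observations(matrix)
    if X.shape[0] < 3:
        raise ValueError("agglomerative coefficient needs at least 3 samples")
    Z = hierarchy.linkage(X, method=method, metric="euclidean")
    first = _first_merge_heights(Z, X.shape[0])
    return float(np.mean(1.0 - first / Z[-1, 2]))


def select_linkage(matrix: TisMatrix, methods=LINKAGE_METHODS) -> tuple[str, dict]:
    """Agglomerative coefficient per linkage method and the winner."""
    coeffs = {m: agglomerative_coefficient(matrix, m) for m in methods}
    return max(coeffs, key=coeffs.get), coeffs


def run_hca(matrix: TisMatrix, method: str = "ward", metric: str = "euclidean") -> HcaResult:
    """Full hierarchical clustering of the samples."""
    X = _observations(matrix)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    Z = hierarchy.linkage(X, method=method, metric=metric)
    first = _first_merge_heights(Z, X.shape[0])
    ac = float(np.mean(1.0 - first / Z[-1, 2])) if X.shape[0] >= 3 else float("nan")
    return HcaResult(method, Z, matrix.sample_ids, ac)


def to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # channels x components
    explained_variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def run_pca(matrix: TisMatrix, n_components: int = 2, scale: bool = False) -> PcaResult:
    """Mean-centered PCA of samples over the m/z channels.

    Sign convention: each component is flipped so its largest-|loading|
    channel has a positive loading, making outputs deterministic.
    """
    X = _observations(matrix)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not 1 <= n_components <= min(n, p):
        raise ValueError(f"n_components must be in [1, {min(n, p)}]")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((S**2).sum())
    comps = [f"PC{k + 1}" for k in range(n_components)]
    loadings = Vt[:n_components].T
    scores = U[:, :n_components] * S[:n_components]
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=comps),
        loadings=pd.DataFrame(loadings, index=matrix.mz_axis, columns=comps),
        explained_variance_fraction=(S[:n_components] ** 2) / total_var,
    )
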