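"""Hierarchical clustering of conformational ensembles and medoid picking.

Agglomerative clustering acts on the raw RMSD dissimilarity matrix for the
single, complete and average linkages, which are well-defined for
arbitrary dissimilarities.  Ward linkage assumes squared Euclidean
geometry, so it is run on a classical-MDS embedding of the matrix instead
(full-rank by default).  Cluster representatives are medoids: the member
minimizing summed dissimilarity to its co-members, ties broken by input
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .embedding import fit_cmds
from .geometry import DissimilarityMatrix

__all__ = ["ClusterResult", "hierarchical_cluster", "medoid_representative", "linkage_to_newick"]

LINKAGES = ("single", "complete", "average", "ward")


@dataclass
class ClusterResult:
    """A flat partition of the ensemble into k conformational clusters."""

    ids: list[str]
    labels: np.ndarray  # per-structure integer cluster id, 1..k
    k: int
    linkage: str
    representatives: dict[int, str]  # cluster id -> medoid structure id
    Z: np.ndarray  # scipy linkage matrix (dendrogram)

    def members(self, cluster: int) -> list[str]:
        return [i for i, lab in zip(self.ids, self.labels) if lab == cluster]


def hierarchical_cluster(
    D: DissimilarityMatrix,
    k: int,
    linkage: str = "average",
    coords: np.ndarray | None = None,
) -> ClusterResult:
    """Cut an agglomerative tree of the ensemble into k flat clusters.

    Parameters
    ----------
    D
        All-pairs dissimilarity matrix.
    k
        Flat cluster count, between 1 and n.
    linkage
        One of ``single``, ``complete``, ``average``, ``ward``.
    coords
        Euclidean coordinates for Ward linkage; if omitted, a full-rank
        cMDS embedding of ``D`` is computed internally.  Ignored for the
        other linkages, which act on ``D`` directly.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    n = D.n
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be between 1 and n={n}")
    if n == 1:
        Z = np.empty((0, 4))
        labels = np.array([1])
    elif linkage == "ward":
        if coords is None:
            import warnings

            with warnings.catch_warnings():
                # a full-rank request may exceed the positive spectrum
                warnings.simplefilter("ignore", UserWarning)
                coords = fit_cmds(D, p=max(1, n - 1)).X
        Z = hierarchy.linkage(pdist(coords), method="ward")
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    else:
        Z = hierarchy.linkage(squareform(D.D, checks=False), method=linkage)
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    reps = medoid_representative(D, labels)
    return ClusterResult(
        ids=list(D.labels),
        labels=np.asarray(labels, dtype=int),
        k=int(len(np.unique(labels))),
        linkage=linkage,
        representatives=reps,
        Z=Z,
    )


def medoid_representative(
    D: DissimilarityMatrix, labels: np.ndarray
) -> dict[int, str]:
    """Per-cluster medoid: minimizer of summed dissimilarity to co-members.

    Ties are broken by input order (``np.argmin`` keeps the first).
    """
    labels = np.asarray(labels)
    if labels.shape != (D.n,):
        raise ValueError("labels length does not match matrix")
    reps: dict[int, str] = {}
    for cluster in np.unique(labels):
        idx = np.flatnonzero(labels == cluster)
        if idx.size == 0:
            raise ValueError(f"cluster {cluster} is empty")
        sums = D.D[np.ix_(idx, idx)].sum(axis=1)
        reps[int(cluster)] = D.labels[idx[int(np.argmin(sums))]]
    return reps


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    if tree.is_leaf():
        return f"({labels[tree.id]});"
    return f"({walk(tree.get_left(), tree.dist)},{walk(tree.get_right(), tree.dist)});"
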