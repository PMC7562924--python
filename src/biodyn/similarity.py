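"""Correlation-contrast similarity matrix and k-neighbor network.

The similarity between two feature vectors is their cosine similarity
down-weighted when the vector magnitudes mismatch,

    S_AB = (2 sqrt(beta) / (1 + beta)) * (A . B) / (|A| |B|),
    beta = |A| / |B|,

a metric motivated by interferometric fringe contrast: it equals the
correlation when amplitudes match (beta = 1) and decays as the amplitude
ratio departs from unity.  The patient network links each node to its k
most similar peers (k = 3 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimilarityMatrix", "AdjacencyNetwork", "correlation_contrast",
           "similarity_matrix", "k_neighbor_adjacency"]


def correlation_contrast(a: np.ndarray, b: np.ndarray) -> float:
    """Amplitude-weighted correlation of two feature vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("correlation contrast is undefined for a zero vector")
    beta = na / nb
    contrast = 2.0 * np.sqrt(beta) / (1.0 + beta)
    return float(contrast * (a @ b) / (na * nb))


@dataclass
class SimilarityMatrix:
    ids: list
    matrix: np.ndarray
    groups: dict = field(default_factory=dict)  # id -> display group

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("similarity matrix must be square over ids")


def _cluster_order(sub: np.ndarray) -> np.ndarray:
    """Average-linkage leaf order on distance 1 - similarity."""
    n = sub.shape[0]
    if n <= 2:
        return np.arange(n)
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    dist = 1.0 - sub
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return np.asarray(hierarchy.leaves_list(Z))


def similarity_matrix(
    vectors: np.ndarray,
    ids: list,
    groups: dict | None = None,
    group_order: tuple = ("resistant", "metastatic", "sensitive"),
    cluster_within: bool = True,
) -> SimilarityMatrix:
    """All pairwise correlation contrasts, display-ordered by group.

    Rows are ordered resistant -> metastatic -> sensitive (any id without
    a group entry goes last) and, within each group, by average-linkage
    clustering on 1 - similarity so that similar patients sit together.
    """
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least two vectors")
    if len(ids) != X.shape[0]:
        raise ValueError("one id per vector required")
    n = X.shape[0]
    S = np.empty((n, n))
    for i in range(n):
        S[i, i] = 1.0
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = correlation_contrast(X[i], X[j])

    groups = groups or {}
    order: list = []
    rank = {g: r for r, g in enumerate(group_order)}
    remaining = list(range(n))
    for g in list(group_order) + [None]:
        members = [i for i in remaining
                   if (groups.get(ids[i]) == g if g is not None
                       else groups.get(ids[i]) not in rank)]
        if not members:
            continue
        members = sorted(members, key=lambda i: ids[i])
        if cluster_within and len(members) > 2:
            sub = S[np.ix_(members, members)]
            members = [members[k] for k in _cluster_order(sub)]
        order.extend(members)
    order_arr = np.asarray(order)
    return SimilarityMatrix(
        ids=[ids[i] for i in order_arr],
        matrix=S[np.ix_(order_arr, order_arr)],
        groups={ids[i]: groups.get(ids[i]) for i in order_arr},
    )


@dataclass
class AdjacencyNetwork:
    """Directed top-k adjacency and its symmetrized (union) view."""

    ids: list
    directed: np.ndarray  # A[i, j] = 1 if j is one of i's top-k neighbors
    k: int

    @property
    def undirected(self) -> np.ndarray:
        return np.maximum(self.directed, self.directed.T)

    def to_networkx(self, sim: SimilarityMatrix | None = None):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.ids)
        und = self.undirected
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                if und[i, j]:
                    attrs = {}
                    if sim is not None:
                        attrs["similarity"] = float(sim.matrix[i, j])
                    g.add_edge(self.ids[i], self.ids[j], **attrs)
        return g


def k_neighbor_adjacency(sim: SimilarityMatrix, k: int = 3) -> AdjacencyNetwork:
    """Link each node to its k most similar nodes (self excluded).

    Ties in similarity break by id order (stable sort), so the network is
    deterministic.
    """
    n = len(sim.ids)
    if k >= n:
        raise ValueError("k must be smaller than the number of nodes")
    if k < 1:
        raise ValueError("k must be >= 1")
    A = np.zeros((n, n))
    for i in range(n):
        others = [j for j in range(n) if j != i]
        # stable sort on (-similarity, id) for deterministic tie-breaks
        others.sort(key=lambda j: (-sim.matrix[i, j], sim.ids[j]))
        for j in others[:k]:
            A[i, j] = 1.0
    return AdjacencyNetwork(ids=list(sim.ids), directed=A, k=k)
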