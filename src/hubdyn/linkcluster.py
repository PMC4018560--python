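"""Link-community detection: clustering connections instead of regions.

Edges of the group graph are clustered so that a brain region (vertex) can
belong to several networks at once — one per link community its connections
fall into. Similarity between two connections sharing a keystone vertex is
the Jaccard coefficient of the *exclusive* first-order neighborhoods of the
non-shared endpoints (or its weighted Tanimoto analog); agglomerative
McQuitty (WPGMA) clustering on ``d = 1 - S`` builds a dendrogram, which is
cut at the level maximizing the partition density ``D``.

Partition density of a link cluster with ``m_c`` connections over ``n_c``
vertices is

    D_c = (m_c - (n_c - 1)) / (n_c (n_c - 1)/2 - (n_c - 1))

i.e. the number of connections beyond a spanning tree, normalized between a
tree (0) and a clique (1). The global score ``D`` is the edge-weighted mean
``D = (1/M) sum_c m_c D_c``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin

from .graphs import GroupGraph

logger = logging.getLogger(__name__)

Edge = tuple[int, int]


# ---------------------------------------------------------------------------
# pairwise edge similarity


def _shared_vertex(e1: Edge, e2: Edge) -> tuple[int, int, int]:
    """Return (keystone, i, j) for two edges sharing exactly one vertex."""
    s1, s2 = set(e1), set(e2)
    shared = s1 & s2
    if len(shared) != 1:
        raise ValueError(
            f"edges {tuple(e1)} and {tuple(e2)} share {len(shared)} vertices; "
            "similarity is defined only for edges sharing exactly one"
        )
    k = shared.pop()
    (i,) = s1 - {k}
    (j,) = s2 - {k}
    return k, i, j


def jaccard_similarity(graph: GroupGraph, e1: Edge, e2: Edge) -> float:
    """Jaccard similarity of two connections sharing a keystone vertex.

    ``S = |n(i) & n(j)| / |n(i) | n(j)|`` where ``i`` and ``j`` are the
    non-shared endpoints and ``n(.)`` is the exclusive first-order
    neighborhood (a vertex is not its own neighbor).
    """
    _, i, j = _shared_vertex(e1, e2)
    nbrs = graph.neighbor_sets()
    ni, nj = nbrs[i], nbrs[j]
    union = ni | nj
    if not union:
        raise ValueError(f"vertices {i} and {j} are isolated")
    return len(ni & nj) / len(union)


def tanimoto_similarity(
    graph: GroupGraph, e1: Edge, e2: Edge, self_weight: bool = False
) -> float:
    """Weighted (Tanimoto) similarity of two connections.

    ``S = w_i . w_j / (|w_i|^2 + |w_j|^2 - w_i . w_j)`` where ``w_i`` holds
    the weights from endpoint ``i`` to every vertex in the exclusive union
    neighborhood ``n(i) | n(j)`` (zero where no connection exists). With
    ``self_weight=True`` a diagonal entry equal to the vertex's mean edge
    weight is appended to its own vector, the variant used by the original
    link-community formulation; the default omits it.

    Reduces exactly to the Jaccard coefficient on unit weights.
    """
    _, i, j = _shared_vertex(e1, e2)
    adj = graph.adjacency()
    wi = adj[i].copy()
    wj = adj[j].copy()
    if not wi.any() or not wj.any():
        raise ValueError(f"vertex {i} or {j} is isolated")
    if self_weight:
        deg = (adj != 0).sum(axis=1)
        wi[i] = adj[i].sum() / deg[i]
        wj[j] = adj[j].sum() / deg[j]
    dot = float(wi @ wj)
    return dot / (float(wi @ wi) + float(wj @ wj) - dot)


def build_similarity(
    graph: GroupGraph, method: str = "tanimoto", self_weight: bool = False
) -> list[tuple[int, int, float]]:
    """Similarity for every unordered pair of adjacent edges.

    Returns ``(edge_index_a, edge_index_b, S)`` triples with ``a < b``; all
    non-adjacent pairs are implicitly ``S = 0`` (distance 1). Uses the
    identity that for zero-diagonal adjacency ``W`` the Tanimoto numerator is
    ``(W @ W)_{ij}`` and ``|w_i|^2`` is the row sum of squares, so all pair
    similarities come from one matrix product.
    """
    if method not in ("jaccard", "tanimoto"):
        raise ValueError(f"unknown similarity method {method!r}")
    if graph.n_edges == 0:
        raise ValueError("empty graph")
    adj = graph.adjacency()
    if method == "jaccard":
        adj = (adj != 0).astype(float)
    if self_weight:
        deg = (adj != 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            diag = np.where(deg > 0, adj.sum(axis=1) / np.maximum(deg, 1), 0.0)
        adj = adj + np.diag(diag)
        # with a diagonal term the numerator gains w_ii*w_ji + w_ij*w_jj and
        # the norms gain w_ii^2 / w_jj^2; the matrix identity still applies
    cross = adj @ adj
    sq = np.einsum("ij,ij->i", adj, adj)

    pairs: list[tuple[int, int, float]] = []
    incident: list[list[int]] = [[] for _ in range(graph.n_vertices)]
    for e, (i, j) in enumerate(graph.edges):
        incident[i].append(e)
        incident[j].append(e)
    edges = graph.edges
    for k, edge_ids in enumerate(incident):
        for a_pos in range(len(edge_ids)):
            ea = edge_ids[a_pos]
            i = int(edges[ea, 0] + edges[ea, 1] - k)
            for b_pos in range(a_pos + 1, len(edge_ids)):
                eb = edge_ids[b_pos]
                j = int(edges[eb, 0] + edges[eb, 1] - k)
                dot = cross[i, j]
                s = dot / (sq[i] + sq[j] - dot)
                lo, hi = (ea, eb) if ea < eb else (eb, ea)
                pairs.append((lo, hi, float(s)))
    return pairs


# ---------------------------------------------------------------------------
# hierarchical clustering and partition density


def mcquitty_cluster(
    similarities: list[tuple[int, int, float]], n_edges: int
) -> np.ndarray:
    """McQuitty (WPGMA) dendrogram over graph edges.

    Distances are ``1 - S`` for adjacent edge pairs and 1 for all others
    (the similarity is undefined there and 1 is the maximal distance).
    Returns a scipy linkage matrix whose leaves are the ``n_edges`` graph
    edges.
    """
    if n_edges < 2:
        warnings.warn("fewer than 2 edges: trivial dendrogram", stacklevel=2)
        return np.empty((0, 4))
    dist = np.ones(n_edges * (n_edges - 1) // 2)
    a = np.array([p[0] for p in similarities], dtype=np.intp)
    b = np.array([p[1] for p in similarities], dtype=np.intp)
    s = np.array([p[2] for p in similarities], dtype=float)
    if len(a):
        idx = n_edges * a - a * (a + 1) // 2 + (b - a - 1)
        dist[idx] = 1.0 - s
    return linkage(dist, method="weighted")


@dataclass
class LinkPartition:
    """A flat assignment of every edge to one connectivity cluster."""

    labels: np.ndarray           # cluster id per edge, 0-based
    m_c: dict[int, int]          # edges per cluster
    n_c: dict[int, int]          # vertices per cluster
    density_c: dict[int, float]  # per-cluster partition density D_c
    density: float               # global partition density D
    n_edges: int

    @property
    def n_clusters(self) -> int:
        return len(self.m_c)


def partition_density(
    labels: np.ndarray, edges: np.ndarray
) -> tuple[float, dict[int, float]]:
    """Global and per-cluster partition density of an edge labeling.

    Single-edge clusters (``n_c = 2``) contribute ``D_c = 0`` by convention
    (the 0/0 tree == clique case).
    """
    labels = np.asarray(labels)
    edges = np.asarray(edges)
    if len(labels) != len(edges):
        raise ValueError("one label per edge required")
    m = len(edges)
    d_c: dict[int, float] = {}
    total = 0.0
    for lab in np.unique(labels):
        sel = labels == lab
        m_c = int(sel.sum())
        if m_c == 0:
            raise ValueError(f"cluster {lab} has no edges")
        n_c = len(np.unique(edges[sel]))
        if n_c <= 2:
            d_c[int(lab)] = 0.0
            continue
        dc = (m_c - (n_c - 1)) / (n_c * (n_c - 1) / 2.0 - (n_c - 1))
        d_c[int(lab)] = dc
        total += 2.0 * m_c * (m_c - (n_c - 1)) / ((n_c - 2) * (n_c - 1))
    return total / m, d_c


def _make_partition(labels: np.ndarray, edges: np.ndarray) -> LinkPartition:
    labels = np.asarray(labels)
    # relabel to dense 0-based ids in order of first appearance
    _, dense = np.unique(labels, return_inverse=True)
    d, d_c = partition_density(dense, edges)
    m_c = {int(k): int(v) for k, v in zip(*np.unique(dense, return_counts=True))}
    n_c = {
        lab: len(np.unique(edges[dense == lab])) for lab in m_c
    }
    return LinkPartition(
        labels=dense, m_c=m_c, n_c=n_c, density_c=d_c, density=float(d),
        n_edges=len(edges),
    )


def cut_levels(dendrogram: np.ndarray, n_edges: int) -> list[np.ndarray]:
    """Every distinct flat partition obtainable by cutting the dendrogram.

    Includes the all-singleton partition (cut below the first merge) and the
    partition after the final merge.
    """
    partitions = [np.arange(n_edges)]
    if len(dendrogram) == 0:
        return partitions
    for h in np.unique(dendrogram[:, 2]):
        partitions.append(fcluster(dendrogram, t=h, criterion="distance") - 1)
    return partitions


def cut_at_max_density(
    dendrogram: np.ndarray, graph: GroupGraph
) -> LinkPartition:
    """Flat partition maximizing the global partition density ``D``.

    ``D`` is evaluated at every distinct merge height; ties are broken
    toward the lower cut (more clusters).
    """
    best: LinkPartition | None = None
    for labels in cut_levels(dendrogram, graph.n_edges):
        cand = _make_partition(labels, graph.edges)
        if best is None or cand.density > best.density + 1e-12:
            best = cand
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# vertex membership


@dataclass
class MembershipMap:
    """Per-vertex view of the link partition."""

    table: pd.DataFrame                    # vertex, degree, n_networks, ...
    vertex_clusters: dict[int, dict[int, int]]  # vertex -> {cluster: edges}

    def networks_of(self, vertex: int) -> list[int]:
        """Cluster ids at a vertex, largest edge count first."""
        vc = self.vertex_clusters.get(vertex, {})
        return sorted(vc, key=lambda c: (-vc[c], c))

    @property
    def eligible_vertices(self) -> np.ndarray:
        t = self.table
        return t.loc[t["eligible"], "vertex"].to_numpy()


def vertex_memberships(
    partition: LinkPartition, graph: GroupGraph, min_second: int = 2
) -> MembershipMap:
    """Map vertices to the networks their connections belong to.

    A vertex is *eligible* for the dynamics analysis when it participates in
    at least two networks and its second-largest network contributes at
    least ``min_second`` of its connections (default 2), so that per-network
    mean strengths are stable.
    """
    vertex_clusters: dict[int, dict[int, int]] = {}
    for (i, j), lab in zip(graph.edges, partition.labels):
        for v in (int(i), int(j)):
            vertex_clusters.setdefault(v, {})[int(lab)] = (
                vertex_clusters.get(v, {}).get(int(lab), 0) + 1
            )
    rows = []
    for v in range(graph.n_vertices):
        vc = vertex_clusters.get(v, {})
        counts = sorted(vc.values(), reverse=True)
        degree = sum(counts)
        second = counts[1] if len(counts) > 1 else 0
        rows.append(
            {
                "vertex": v,
                "degree": degree,
                "n_networks": len(counts),
                "second_largest": second,
                "eligible": len(counts) >= 2 and second >= min_second,
            }
        )
    return MembershipMap(table=pd.DataFrame(rows), vertex_clusters=vertex_clusters)


# ---------------------------------------------------------------------------
# estimator facade


class LinkCommunities(ClusterMixin, BaseEstimator):
    """Link-community clustering as a scikit-learn style estimator.

    Fits on a symmetric weighted adjacency matrix (zero meaning "no
    connection"); connections are the samples being clustered, so
    ``labels_`` has one entry per edge of the graph, not per vertex.

    Parameters
    ----------
    method : {"tanimoto", "jaccard"}, default="tanimoto"
        Edge-pair similarity: weighted Tanimoto or binary Jaccard.
    self_weight : bool, default=False
        Include the original link-community self-weight diagonal term in the
        Tanimoto vectors.
    min_second : int, default=2
        Eligibility rule for multi-network vertices (see
        :func:`vertex_memberships`).

    Attributes
    ----------
    graph_ : GroupGraph
        The graph whose edges were clustered.
    labels_ : ndarray of shape (n_edges,)
        Cluster id per edge.
    linkage_ : ndarray
        scipy linkage matrix of the McQuitty dendrogram.
    partition_ : LinkPartition
        Partition at the density-maximizing cut.
    partition_density_ : float
        Global partition density ``D`` at the chosen cut.
    memberships_ : MembershipMap
        Per-vertex network membership view.
    n_clusters_ : int
    """

    def __init__(
        self,
        method: str = "tanimoto",
        self_weight: bool = False,
        min_second: int = 2,
    ):
        self.method = method
        self.self_weight = self_weight
        self.min_second = min_second

    def fit(self, X, y=None):
        """Cluster the connections of a graph.

        ``X`` may be a :class:`GroupGraph` or a symmetric (P, P) weighted
        adjacency matrix.
        """
        if isinstance(X, GroupGraph):
            graph = X
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[0] != X.shape[1]:
                raise ValueError("X must be a square adjacency matrix")
            if not np.allclose(X, X.T):
                raise ValueError("adjacency matrix must be symmetric")
            iu, ju = np.nonzero(np.triu(X, k=1))
            graph = GroupGraph(
                n_vertices=X.shape[0],
                edges=np.column_stack([iu, ju]),
                weights=X[iu, ju],
            )
        sims = build_similarity(graph, self.method, self.self_weight)
        self.graph_ = graph
        self.linkage_ = mcquitty_cluster(sims, graph.n_edges)
        if graph.n_edges < 2:
            self.partition_ = _make_partition(
                np.zeros(graph.n_edges, dtype=int), graph.edges
            )
        else:
            self.partition_ = cut_at_max_density(self.linkage_, graph)
        self.labels_ = self.partition_.labels
        self.partition_density_ = self.partition_.density
        self.n_clusters_ = self.partition_.n_clusters
        self.memberships_ = vertex_memberships(
            self.partition_, graph, self.min_second
        )
        return self

    def fit_predict(self, X, y=None):
        """Fit and return the per-edge cluster labels."""
        return self.fit(X).labels_
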