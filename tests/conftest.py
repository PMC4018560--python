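"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from hubdyn import GroupGraph, SimulationConfig


# ---------------------------------------------------------------------------
# minimal worked-example graphs


@pytest.fixture
def low_similarity_graph() -> GroupGraph:
    """Two connections whose non-shared endpoints share only the keystone.

    Vertices i=0, j=1, k=2, a=3, b=4; edges i-k, j-k, i-a, j-b.
    """
    return GroupGraph(5, [(0, 2), (1, 2), (0, 3), (1, 4)], [1.0] * 4)


@pytest.fixture
def identical_neighborhood_graph() -> GroupGraph:
    """Two connections whose non-shared endpoints have identical
    neighborhoods: i=0 and j=1 each connect to k=2, a=3, b=4."""
    return GroupGraph(
        5, [(0, 2), (1, 2), (0, 3), (1, 3), (0, 4), (1, 4)], [1.0] * 6
    )


def random_graph(
    rng: np.random.Generator,
    n_vertices: int = 8,
    n_edges: int = 8,
    weighted: bool = True,
) -> GroupGraph:
    """Random simple graph with exactly ``n_edges`` edges."""
    iu, ju = np.triu_indices(n_vertices, k=1)
    pick = rng.choice(len(iu), size=n_edges, replace=False)
    pick.sort()
    w = rng.uniform(0.2, 2.0, size=n_edges) if weighted else np.ones(n_edges)
    return GroupGraph(n_vertices, np.column_stack([iu[pick], ju[pick]]), w)


# ---------------------------------------------------------------------------
# independent oracles


def wpgma_reference(dist: np.ndarray) -> list[float]:
    """Textbook WPGMA (McQuitty) agglomeration on a dense distance matrix.

    Merges the closest pair, replacing it by a node whose distance to any
    other cluster is the plain average of the two constituents' distances.
    Returns the sorted merge heights (order-free comparison).
    """
    d = dist.astype(float).copy()
    n = d.shape[0]
    active = list(range(n))
    heights = []
    while len(active) > 1:
        best = (np.inf, None)
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                dd = d[active[ai], active[bi]]
                if dd < best[0]:
                    best = (dd, (ai, bi))
        h, (ai, bi) = best
        heights.append(h)
        a, b = active[ai], active[bi]
        merged = (d[a] + d[b]) / 2.0
        d[a, :] = merged
        d[:, a] = merged
        d[a, a] = 0.0
        active.pop(bi)
    return sorted(heights)


def brute_force_adjacent_pairs(graph: GroupGraph) -> set[tuple[int, int]]:
    """All unordered edge pairs sharing exactly one vertex, by double loop."""
    out = set()
    edges = [tuple(e) for e in graph.edges]
    for a in range(len(edges)):
        for b in range(a + 1, len(edges)):
            if len(set(edges[a]) & set(edges[b])) == 1:
                out.add((a, b))
    return out


def direct_partition_density(labels, edges) -> float:
    """Direct evaluation of the global partition density formula
    D = (2/M) * sum_c m_c * (m_c - (n_c - 1)) / ((n_c - 2)(n_c - 1))."""
    labels = np.asarray(labels)
    edges = np.asarray(edges)
    m = len(edges)
    total = 0.0
    for lab in set(labels.tolist()):
        sel = labels == lab
        m_c = int(sel.sum())
        n_c = len({int(v) for e in edges[sel] for v in e})
        if n_c > 2:
            total += m_c * (m_c - (n_c - 1)) / ((n_c - 2) * (n_c - 1))
    return 2.0 * total / m


def exhaustive_best_cut_density(dendrogram, edges) -> float:
    """Maximum partition density over every flat cut of a dendrogram.

    Replays the merge list with union-find at every threshold between
    consecutive merge heights (plus the extremes) and evaluates D directly.
    """
    m = len(edges)
    heights = sorted(set(dendrogram[:, 2].tolist())) if len(dendrogram) else []
    thresholds = [-1.0] + heights
    best = -np.inf
    for t in thresholds:
        parent = list(range(m + len(dendrogram)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for k, (left, right, h, _) in enumerate(dendrogram):
            if h <= t:
                node = m + k
                parent[find(int(left))] = node
                parent[find(int(right))] = node
        labels = np.array([find(e) for e in range(m)])
        best = max(best, direct_partition_density(labels, edges))
    return best


# ---------------------------------------------------------------------------
# synthetic cohorts (scaled down for speed where allowed)


def small_cohort_config(seed: int = 0, n_subjects: int = 20, **kw) -> SimulationConfig:
    """30-parcel, two-community cohort with one switching hub."""
    defaults = dict(
        seed=seed,
        n_subjects=n_subjects,
        n_parcels=30,
        n_timepoints=330,
        state_block_length=30,
        communities=[list(range(0, 16)), list(range(15, 30))],
        hub_parcels=[(15, 0, 1)],
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest structured cohort reused across tests (read-only)."""
    from hubdyn import simulate_cohort

    return simulate_cohort(small_cohort_config(seed=42))
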