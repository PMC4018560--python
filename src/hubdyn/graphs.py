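"""Group-level connectivity graph construction.

Per-subject parcel time series are turned into Pearson correlation matrices,
Fisher z-transformed (variance-stabilizing, so values can be averaged and
differenced), averaged over subjects, and thresholded by keeping only the
top fraction of connections. The retained connections, weighted by their
group-mean z value, form the group graph on which all downstream edge
clustering and dynamics operate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: correlations are clamped to +/- this value before atanh so that perfectly
#: collinear parcels yield a large finite z instead of infinity
R_CLAMP = 1.0 - 1e-7


class DegenerateSeriesError(ValueError):
    """A parcel time series is constant, so its correlation is undefined."""


@dataclass
class SubjectTimeSeries:
    """One subject's parcel signals.

    Parameters
    ----------
    subject_id : str
        Identifier used to join with the behavioral table.
    data : ndarray of shape (T, P)
        Signal value per timepoint (rows) and parcel (columns), arbitrary
        units.
    tr : float
        Sampling interval (repetition time) in seconds.
    """

    subject_id: str
    data: np.ndarray
    tr: float = 0.645

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError(
                f"subject {self.subject_id}: need a T x P matrix with T >= 2, "
                f"got shape {self.data.shape}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    def constant_parcels(self) -> np.ndarray:
        """Indices of parcels with zero variance (flagged, not removed)."""
        return np.flatnonzero(self.data.std(axis=0) == 0)


@dataclass
class GroupGraph:
    """Thresholded group connectivity graph.

    Vertices are parcel indices ``0..P-1``; edges are stored as an
    ``(k, 2)`` integer array with ``i < j`` per row, weighted by the
    group-mean Fisher z value.
    """

    n_vertices: int
    edges: np.ndarray
    weights: np.ndarray
    sparsity: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.intp).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if len(self.edges) != len(self.weights):
            raise ValueError("edges and weights length mismatch")
        if np.any(self.edges[:, 0] >= self.edges[:, 1]):
            raise ValueError("edges must satisfy i < j")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric weighted adjacency matrix (zero diagonal)."""
        a = np.zeros((self.n_vertices, self.n_vertices))
        i, j = self.edges.T
        a[i, j] = self.weights
        a[j, i] = self.weights
        return a

    def neighbor_sets(self) -> list[set[int]]:
        """Exclusive first-order neighborhood of every vertex."""
        nbrs: list[set[int]] = [set() for _ in range(self.n_vertices)]
        for (i, j) in self.edges:
            nbrs[i].add(int(j))
            nbrs[j].add(int(i))
        return nbrs

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_vertices, dtype=int)
        for (i, j) in self.edges:
            d[i] += 1
            d[j] += 1
        return d

    def incident_edges(self, vertex: int) -> np.ndarray:
        """Indices of edges touching ``vertex``."""
        return np.flatnonzero(
            (self.edges[:, 0] == vertex) | (self.edges[:, 1] == vertex)
        )


def fisher_z_connectivity(ts: SubjectTimeSeries) -> np.ndarray:
    """Fisher z-transformed Pearson correlation matrix of one subject.

    Entry ``(i, j)`` is ``atanh(r_ij)`` with ``|r|`` clamped at
    ``1 - 1e-7`` so collinear parcels give a large finite value. The
    diagonal (undefined self-connectivity) is set to 0 and ignored
    downstream.

    Raises
    ------
    DegenerateSeriesError
        If any parcel has a constant signal.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    constant = ts.constant_parcels()
    if constant.size:
        raise DegenerateSeriesError(
            f"subject {ts.subject_id}: constant signal in parcel(s) "
            f"{constant.tolist()}"
        )
    r = np.corrcoef(ts.data, rowvar=False)
    np.clip(r, -R_CLAMP, R_CLAMP, out=r)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return z


def group_average(zmats: list[np.ndarray]) -> np.ndarray:
    """Elementwise arithmetic mean of per-subject Fisher z matrices."""
    if not zmats:
        raise ValueError("no z-matrices to average")
    shapes = {m.shape for m in zmats}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent matrix shapes: {sorted(shapes)}")
    return np.mean(np.stack(zmats), axis=0)


def _edge_count(p: int, sparsity: float) -> int:
    return int(round(sparsity * p * (p - 1) / 2.0))


def threshold_top_fraction(
    groupz: np.ndarray,
    sparsity: float | None = None,
    n_edges: int | None = None,
) -> GroupGraph:
    """Keep the strongest fraction (or absolute number) of connections.

    The ``k = round(sparsity * P(P-1)/2)`` largest upper-triangle values
    become weighted edges. Ties at the threshold boundary are broken
    deterministically by lexicographic ``(i, j)`` order. Exactly one of
    ``sparsity`` and ``n_edges`` must be given.
    """
    p = groupz.shape[0]
    if groupz.shape != (p, p):
        raise ValueError("group z-matrix must be square")
    n_pairs = p * (p - 1) // 2
    if (sparsity is None) == (n_edges is None):
        raise ValueError("give exactly one of sparsity or n_edges")
    if sparsity is not None:
        if not 0 < sparsity <= 1:
            raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
        k = _edge_count(p, sparsity)
    else:
        k = int(n_edges)
        sparsity = k / n_pairs
    if k <= 0:
        raise ValueError("thresholding would retain zero edges")
    if k > n_pairs:
        raise ValueError(f"requested {k} edges but only {n_pairs} pairs exist")

    iu, ju = np.triu_indices(p, k=1)
    w = groupz[iu, ju]
    # sort by weight descending, then (i, j) ascending for determinism
    order = np.lexsort((ju, iu, -w))[:k]
    keep = np.sort(order)
    edges = np.column_stack([iu[keep], ju[keep]])
    return GroupGraph(
        n_vertices=p, edges=edges, weights=w[keep], sparsity=float(sparsity)
    )


def build_group_graph(
    subjects: list[SubjectTimeSeries],
    sparsity: float | None = 0.10,
    n_edges: int | None = None,
) -> GroupGraph:
    """Full graph-construction stage: correlate, z-transform, average,
    threshold."""
    zmats = [fisher_z_connectivity(ts) for ts in subjects]
    return threshold_top_fraction(group_average(zmats), sparsity, n_edges)
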