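"""Sliding-window connectivity dynamics and variation of network participation.

Each subject's scan is split into consecutive non-overlapping windows of
``w`` volumes; per-window edge correlations are Fisher z-transformed and
expressed as *change scores* relative to the subject's full-scan baseline z.
A multi-network hub's variation of network participation (VNP) is the mean
squared error between the per-window mean change of its connections in one
network and in another; significance comes from a permutation null that
redraws same-sized connection sets from the hub irrespective of network
labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .graphs import R_CLAMP, GroupGraph, SubjectTimeSeries
from .linkcluster import LinkPartition, MembershipMap

logger = logging.getLogger(__name__)

#: default window length in volumes; at TR = 0.645 s this is 49.7 s
DEFAULT_WINDOW = 77


def window_duration(window: int, tr: float) -> float:
    """Window length in seconds (volumes times sampling interval)."""
    return window * tr


@dataclass
class WindowedZ:
    """Per-edge, per-window Fisher z values for one subject."""

    subject_id: str
    z: np.ndarray          # (E, W)
    baseline: np.ndarray   # (E,) full-scan z per edge
    window: int            # volumes per window

    @property
    def n_windows(self) -> int:
        return self.z.shape[1]


def _windowed_edge_corr(data: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Pearson r per edge for one block of samples; constant parcels give 0."""
    c = data - data.mean(axis=0)
    ss = np.einsum("ti,ti->i", c, c)
    i, j = edges.T
    num = np.einsum("ti,ti->i", c[:, i], c[:, j])
    den = np.sqrt(ss[i] * ss[j])
    bad = den == 0
    if bad.any():
        logger.warning("constant parcel within a window on %d edge(s)", bad.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(bad, 0.0, num / np.where(bad, 1.0, den))
    return np.clip(r, -R_CLAMP, R_CLAMP)


def window_fisher_z(
    ts: SubjectTimeSeries, edges: np.ndarray, window: int = DEFAULT_WINDOW
) -> WindowedZ:
    """Non-overlapping sliding-window Fisher z per edge.

    Window ``t`` covers samples ``[t*w, (t+1)*w - 1]``; the trailing
    ``T - W*w`` samples are discarded. The full-scan baseline z uses all
    ``T`` samples.
    """
    if window < 3:
        raise ValueError("window must be at least 3 volumes")
    t_total = ts.n_timepoints
    n_win = t_total // window
    if n_win < 2:
        logger.warning(
            "subject %s: only %d window(s) of length %d fit in %d samples",
            ts.subject_id, n_win, window, t_total,
        )
    if n_win == 0:
        raise ValueError(f"scan shorter ({t_total}) than one window ({window})")
    edges = np.asarray(edges, dtype=np.intp).reshape(-1, 2)
    z = np.empty((len(edges), n_win))
    for t in range(n_win):
        block = ts.data[t * window:(t + 1) * window]
        z[:, t] = np.arctanh(_windowed_edge_corr(block, edges))
    baseline = np.arctanh(_windowed_edge_corr(ts.data, edges))
    return WindowedZ(ts.subject_id, z=z, baseline=baseline, window=window)


def baseline_normalize(wz: WindowedZ) -> np.ndarray:
    """Change scores: windowed z minus the subject's full-scan baseline z."""
    return wz.z - wz.baseline[:, None]


def change_tensor(
    subjects: list[SubjectTimeSeries],
    edges: np.ndarray,
    window: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """Stack of per-subject change matrices, shape (S, E, W)."""
    return np.stack(
        [baseline_normalize(window_fisher_z(ts, edges, window)) for ts in subjects]
    )


# ---------------------------------------------------------------------------
# within- vs between-cluster change variance


@dataclass
class ClusterVarianceResult:
    """Within-cluster vs pooled change variance at one region."""

    region: int
    var_within: dict[int, float]   # mean within-cluster variance per cluster
    var_across: float              # mean pooled variance over all its edges
    statistic: dict[int, float]    # Wilcoxon W per cluster
    p_value: dict[int, float]      # one-sided p (within < across)


def cluster_change_variances(
    changes: np.ndarray,
    region_labels: np.ndarray,
    region: int = -1,
) -> ClusterVarianceResult:
    """Test whether connection changes co-vary more within than across
    networks.

    ``changes`` holds one region's connections, shape (S, E_r, W), and
    ``region_labels`` their cluster ids. For every (subject, window)
    observation the variance of change across the connections of each
    cluster is compared with the variance across all the region's
    connections pooled, by a one-sided paired Wilcoxon signed-rank test.
    Observations where both variances tie (e.g. all connections changing
    identically) contribute ties; an all-tie sample is reported as p = 1.
    """
    changes = np.asarray(changes)
    if changes.ndim == 2:
        changes = changes[None]
    s, e_r, w = changes.shape
    region_labels = np.asarray(region_labels)
    clusters = np.unique(region_labels)
    if len(clusters) < 2 or any(
        (region_labels == c).sum() < 2 for c in clusters
    ):
        raise ValueError(
            "region needs >= 2 networks with >= 2 connections each"
        )
    if s * w < 6:
        raise ValueError(
            f"only {s * w} (subject, window) observations; need >= 6"
        )
    flat = changes.reshape(s, e_r, w)
    var_across = flat.var(axis=1, ddof=1)          # (S, W)
    res_vw: dict[int, float] = {}
    res_stat: dict[int, float] = {}
    res_p: dict[int, float] = {}
    for c in clusters:
        vw = flat[:, region_labels == c, :].var(axis=1, ddof=1)  # (S, W)
        diff = (vw - var_across).ravel()
        if np.all(diff == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = wilcoxon(
                vw.ravel(), var_across.ravel(), alternative="less",
                zero_method="wilcox",
            )
        res_vw[int(c)] = float(vw.mean())
        res_stat[int(c)] = float(stat)
        res_p[int(c)] = float(p)
    return ClusterVarianceResult(
        region=region,
        var_within=res_vw,
        var_across=float(var_across.mean()),
        statistic=res_stat,
        p_value=res_p,
    )


# ---------------------------------------------------------------------------
# VNP: variation of network participation


def region_edge_view(
    graph: GroupGraph, partition: LinkPartition, region: int
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and cluster labels of a region's connections."""
    idx = graph.incident_edges(region)
    return idx, partition.labels[idx]


def hub_network_timecourses(
    changes: np.ndarray, region_labels: np.ndarray
) -> dict[int, np.ndarray]:
    """Per-network mean change timecourse at a hub.

    ``changes`` is (S, E_r, W) (or (E_r, W) for one subject) over the hub's
    connections; returns, per cluster with at least one connection, the
    arithmetic mean over that cluster's connections: shape (S, W).
    """
    changes = np.asarray(changes)
    squeeze = changes.ndim == 2
    if squeeze:
        changes = changes[None]
    region_labels = np.asarray(region_labels)
    out: dict[int, np.ndarray] = {}
    for c in np.unique(region_labels):
        tc = changes[:, region_labels == c, :].mean(axis=1)
        out[int(c)] = tc[0] if squeeze else tc
    return out


def vnp_mse(tc_a: np.ndarray, tc_b: np.ndarray) -> float:
    """Mean squared error between two mean-strength timecourses."""
    tc_a = np.asarray(tc_a, dtype=float)
    tc_b = np.asarray(tc_b, dtype=float)
    if tc_a.shape != tc_b.shape:
        raise ValueError(f"shape mismatch {tc_a.shape} vs {tc_b.shape}")
    if tc_a.shape[-1] < 2:
        raise ValueError("need at least 2 windows")
    return float(np.mean((tc_a - tc_b) ** 2))


def _mean_pairwise_mse(changes: np.ndarray, groups: list[np.ndarray]) -> float:
    """Mean over network pairs of the MSE between mean timecourses.

    ``changes`` is (S, E_r, W); ``groups`` index arrays into axis 1.
    """
    means = [changes[:, g, :].mean(axis=1) for g in groups]
    mses = [
        np.mean((means[a] - means[b]) ** 2)
        for a, b in combinations(range(len(means)), 2)
    ]
    return float(np.mean(mses))


def permutation_test_vnp(
    changes: np.ndarray,
    sizes: tuple[int, ...],
    n_perm: int = 10_000,
    seed: int | None = None,
    observed: float | None = None,
    region_labels: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Random-cluster permutation null for a hub's VNP.

    Each permutation draws disjoint connection sets of the given ``sizes``
    from the hub's connections without regard to their network labels and
    computes the mean pairwise MSE between the sets' mean timecourses. The
    observed VNP is either supplied or computed from ``region_labels``.
    Returns the null distribution and the add-one permutation p-value
    ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    changes = np.asarray(changes)
    if changes.ndim == 2:
        changes = changes[None]
    e_r = changes.shape[1]
    sizes = tuple(int(m) for m in sizes)
    if len(sizes) < 2 or any(m < 1 for m in sizes):
        raise ValueError("need at least two non-empty cluster sizes")
    if sum(sizes) > e_r:
        raise ValueError(
            f"cluster sizes {sizes} exceed the region's {e_r} connections"
        )
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if observed is None:
        if region_labels is None:
            raise ValueError("give observed VNP or region_labels")
        region_labels = np.asarray(region_labels)
        groups = [
            np.flatnonzero(region_labels == c)
            for c in np.unique(region_labels)
        ]
        observed = _mean_pairwise_mse(changes, groups)
    rng = np.random.default_rng(seed)
    bounds = np.cumsum((0,) + sizes)
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(e_r)
        groups = [perm[bounds[g]:bounds[g + 1]] for g in range(len(sizes))]
        null[p] = _mean_pairwise_mse(changes, groups)
    p_value = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return null, float(p_value)


def whole_brain_vnp(
    changes: np.ndarray,
    graph: GroupGraph,
    partition: LinkPartition,
    memberships: MembershipMap,
    subject_ids: list[str] | None = None,
    n_perm: int = 0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region-level and subject-level variation of network participation.

    A region's VNP (per subject) is the unweighted mean, over all pairs of
    networks it participates in, of the MSE between the pair's mean change
    timecourses; a subject's whole-brain VNP is the unweighted mean over
    eligible regions. With ``n_perm > 0`` a random-cluster permutation p is
    attached per region.

    Returns ``(region_table, subject_table)``.
    """
    changes = np.asarray(changes)
    if changes.ndim == 2:
        changes = changes[None]
    n_subj = changes.shape[0]
    if subject_ids is None:
        subject_ids = [str(s) for s in range(n_subj)]
    eligible = memberships.eligible_vertices
    if eligible.size == 0:
        raise ValueError("no eligible multi-network regions")
    rng = np.random.default_rng(seed)
    rows = []
    per_subject = np.zeros((n_subj, len(eligible)))
    memb = memberships.table.set_index("vertex")
    for col, region in enumerate(eligible):
        idx, labels = region_edge_view(graph, partition, int(region))
        tcs = hub_network_timecourses(changes[:, idx, :], labels)
        nets = sorted(tcs)
        pair_mses = np.stack(
            [
                ((tcs[a] - tcs[b]) ** 2).mean(axis=1)
                for a, b in combinations(nets, 2)
            ]
        )                                   # (n_pairs, S)
        region_vnp = pair_mses.mean(axis=0)  # per subject
        per_subject[:, col] = region_vnp
        row = {
            "region": int(region),
            "degree": int(memb.loc[region, "degree"]),
            "n_networks": int(memb.loc[region, "n_networks"]),
            "vnp": float(region_vnp.mean()),
        }
        if n_perm:
            sizes = tuple(int((labels == c).sum()) for c in nets)
            _, p = permutation_test_vnp(
                changes[:, idx, :],
                sizes,
                n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)),
                observed=float(region_vnp.mean()),
            )
            row["p_perm"] = p
        rows.append(row)
    region_table = pd.DataFrame(rows)
    subject_table = pd.DataFrame(
        {"subject_id": subject_ids, "whole_brain_vnp": per_subject.mean(axis=1)}
    )
    return region_table, subject_table
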