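"""Clustering reliability and behavioral association statistics.

Reliability of the link clustering is assessed by a split-half design: the
edge set is fixed from the full group, edge weights and dendrograms are
recomputed on odd- and even-indexed subject halves, and the two dendrograms
are compared through the Pearson correlation of their cophenetic distance
vectors, with a Mantel permutation null (leaf-label permutations).

Behavioral associations use partial Spearman correlations — Pearson
correlation of covariate-residualized ranks — with Bonferroni correction
over the test battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform
from scipy.stats import rankdata, t as t_dist

from .graphs import (
    SubjectTimeSeries,
    fisher_z_connectivity,
    group_average,
    build_group_graph,
    GroupGraph,
)
from .linkcluster import build_similarity, mcquitty_cluster


# ---------------------------------------------------------------------------
# split-half reliability


def cophenetic_vector(dendrogram: np.ndarray) -> np.ndarray:
    """Condensed cophenetic distances (lowest common merge height per leaf
    pair)."""
    return cophenet(dendrogram)


def mantel_test(
    vec_a: np.ndarray,
    vec_b: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel permutation test between two condensed distance vectors.

    Permutes the leaf labels underlying ``vec_b`` (rows and columns of its
    square form jointly) and recomputes the Pearson correlation with
    ``vec_a``; one-sided p for the observed correlation being large.
    """
    vec_a = np.asarray(vec_a, dtype=float)
    vec_b = np.asarray(vec_b, dtype=float)
    if vec_a.shape != vec_b.shape:
        raise ValueError("cophenetic vectors differ in length")
    obs = float(np.corrcoef(vec_a, vec_b)[0, 1])
    sq_b = squareform(vec_b, checks=False)
    m = sq_b.shape[0]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(m)
        null = float(
            np.corrcoef(vec_a, squareform(sq_b[np.ix_(perm, perm)], checks=False))[
                0, 1
            ]
        )
        if null >= obs:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return obs, p


def _half_dendrogram(
    subjects: list[SubjectTimeSeries],
    graph: GroupGraph,
    method: str,
    self_weight: bool,
) -> np.ndarray:
    """Dendrogram over the fixed edge set with weights from a subject half."""
    z = group_average([fisher_z_connectivity(ts) for ts in subjects])
    i, j = graph.edges.T
    half = GroupGraph(
        n_vertices=graph.n_vertices,
        edges=graph.edges,
        weights=z[i, j],
        sparsity=graph.sparsity,
    )
    sims = build_similarity(half, method=method, self_weight=self_weight)
    return mcquitty_cluster(sims, half.n_edges)


def split_half_reliability(
    subjects: list[SubjectTimeSeries],
    sparsity: float | None = 0.10,
    n_edges: int | None = None,
    method: str = "tanimoto",
    self_weight: bool = False,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Split-half reliability of the link clustering.

    Fixes the connection set from the full-group graph, re-estimates edge
    weights and dendrograms on the odd- and even-indexed subject halves,
    and returns ``(cophenetic_r, mantel_p)``.
    """
    if len(subjects) < 4:
        raise ValueError("need at least 4 subjects for a split-half test")
    graph = build_group_graph(subjects, sparsity=sparsity, n_edges=n_edges)
    evens = subjects[0::2]
    odds = subjects[1::2]
    dendro_even = _half_dendrogram(evens, graph, method, self_weight)
    dendro_odd = _half_dendrogram(odds, graph, method, self_weight)
    return mantel_test(
        cophenetic_vector(dendro_even),
        cophenetic_vector(dendro_odd),
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# partial Spearman correlation


@dataclass
class AssociationResult:
    """One partial-correlation test."""

    x: str
    y: str
    covariates: list[str] = field(default_factory=list)
    n: int = 0
    r: float = float("nan")
    p: float = float("nan")
    p_corrected: float = float("nan")

    def to_row(self) -> dict:
        return {
            "x": self.x,
            "y": self.y,
            "covariates": ";".join(self.covariates),
            "n": self.n,
            "r": self.r,
            "p": self.p,
            "p_corrected": self.p_corrected,
        }


def _residualize(ranks: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, ranks, rcond=None)
    return ranks - design @ beta


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    x_name: str = "x",
    y_name: str = "y",
) -> AssociationResult:
    """Partial Spearman correlation of ``x`` and ``y`` given covariates.

    All variables are rank-transformed; the ranks of ``x`` and ``y`` are
    residualized on the covariate ranks (with intercept) by least squares,
    and the Pearson correlation of the residuals is returned with its
    t-distribution p-value at ``df = n - 2 - n_covariates``. With no
    covariates this is the ordinary Spearman correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y differ in length")
    cov_names: list[str] = []
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        if isinstance(covariates, pd.DataFrame):
            cov_names = [str(c) for c in covariates.columns]
            cov = covariates.to_numpy(dtype=float)
        else:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            cov_names = [f"c{i}" for i in range(cov.shape[1])]
        if len(cov) != n:
            raise ValueError("covariates differ in length")
    k = cov.shape[1]
    if n < k + 3:
        raise ValueError(f"n={n} too small for {k} covariates")
    if np.isnan(x).any() or np.isnan(y).any() or np.isnan(cov).any():
        raise ValueError("missing values are not allowed")
    rx = rankdata(x)
    ry = rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant variable after ranking")
    design = np.column_stack(
        [np.ones(n)] + [rankdata(cov[:, c]) for c in range(k)]
    )
    ex = _residualize(rx, design)
    ey = _residualize(ry, design)
    # a variable fully explained by the covariates has a residual of pure
    # rounding noise; report zero partial correlation instead of noise
    scale_x = np.linalg.norm(rx - rx.mean())
    scale_y = np.linalg.norm(ry - ry.mean())
    nx, ny = np.linalg.norm(ex), np.linalg.norm(ey)
    if nx <= 1e-10 * scale_x or ny <= 1e-10 * scale_y:
        r = 0.0
    else:
        r = float(ex @ ey) / (nx * ny)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t_stat = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * t_dist.sf(abs(t_stat), df))
    return AssociationResult(
        x=x_name, y=y_name, covariates=cov_names, n=n, r=r, p=p
    )


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: ``min(1, p * m)``."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError("m must be at least 1")
    return min(1.0, p * m)


# ---------------------------------------------------------------------------
# association suite


@dataclass
class AssociationSpec:
    """One requested test: x against y given covariates, corrected for m."""

    x: str
    y: str
    covariates: list[str]
    m: int = 1


def default_association_spec(
    content: list[str] | None = None,
    form: list[str] | None = None,
    regions: list[int] | None = None,
) -> list[AssociationSpec]:
    """The standard test battery.

    Whole-brain VNP against each content factor (covariates: motion, age,
    gender and the other content factors; corrected for the 8 factor
    tests), against each form factor likewise, and against age (covariate:
    motion). With ``regions`` given, per-region VNP columns
    (``vnp_region_<r>``) are tested against all factors, corrected for
    ``8 * n_regions`` comparisons.
    """
    from .synthdata import CONTENT_FACTORS, FORM_FACTORS

    content = CONTENT_FACTORS if content is None else content
    form = FORM_FACTORS if form is None else form
    n_factors = len(content) + len(form)
    spec: list[AssociationSpec] = []
    for factor in content:
        others = [f for f in content if f != factor]
        spec.append(
            AssociationSpec(
                x="whole_brain_vnp",
                y=factor,
                covariates=["micromovement", "age", "gender", *others],
                m=n_factors,
            )
        )
    for factor in form:
        others = [f for f in form if f != factor]
        spec.append(
            AssociationSpec(
                x="whole_brain_vnp",
                y=factor,
                covariates=["micromovement", "age", "gender", *others],
                m=n_factors,
            )
        )
    spec.append(
        AssociationSpec(
            x="whole_brain_vnp", y="age", covariates=["micromovement"], m=1
        )
    )
    if regions:
        m = n_factors * len(regions)
        for r in regions:
            for factor in [*content, *form]:
                spec.append(
                    AssociationSpec(
                        x=f"vnp_region_{r}",
                        y=factor,
                        covariates=["micromovement", "age", "gender"],
                        m=m,
                    )
                )
    return spec


def run_association_suite(
    vnp_table: pd.DataFrame,
    behavior: pd.DataFrame,
    spec: list[AssociationSpec],
) -> pd.DataFrame:
    """Run a battery of partial Spearman tests on the joined tables.

    ``vnp_table`` must carry ``subject_id`` plus VNP columns; ``behavior``
    the factor scores and covariates. Tables are inner-joined on
    ``subject_id`` and an error names any subject missing from either side.
    """
    missing = set(vnp_table["subject_id"]) ^ set(behavior["subject_id"])
    if missing:
        raise ValueError(
            f"subjects missing from one table: {sorted(missing)}"
        )
    joined = vnp_table.merge(behavior, on="subject_id", validate="1:1")
    rows = []
    for item in spec:
        res = partial_spearman(
            joined[item.x].to_numpy(),
            joined[item.y].to_numpy(),
            joined[item.covariates] if item.covariates else None,
            x_name=item.x,
            y_name=item.y,
        )
        res.covariates = list(item.covariates)
        res.p_corrected = bonferroni(res.p, item.m)
        rows.append(res.to_row())
    return pd.DataFrame(rows)
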