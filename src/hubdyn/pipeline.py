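"""End-to-end pipeline: graph -> link clustering -> dynamics -> associations.

A single seed in the configuration is split deterministically into
per-stage substreams so reruns with the same configuration are bit-identical
while stages stay independent.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .associations import (
    AssociationSpec,
    default_association_spec,
    run_association_suite,
    split_half_reliability,
)
from .dynamics import change_tensor, whole_brain_vnp, DEFAULT_WINDOW
from .graphs import SubjectTimeSeries, build_group_graph, GroupGraph
from .linkcluster import LinkCommunities

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Everything needed for a full run."""

    timeseries_manifest: str | None = None
    behavior_table: str | None = None
    output_dir: str = "hubdyn_out"
    sparsity: float | None = 0.10
    n_edges: int | None = None
    method: str = "tanimoto"
    self_weight: bool = False
    window: int = DEFAULT_WINDOW
    n_perm: int = 10_000
    min_second: int = 2
    seed: int = 0

    def validate(self) -> None:
        if (self.sparsity is None) == (self.n_edges is None):
            raise ValueError("set exactly one of sparsity or n_edges")
        if self.sparsity is not None and not 0 < self.sparsity <= 1:
            raise ValueError("sparsity must be in (0, 1]")
        if self.window < 3:
            raise ValueError("window must be >= 3 volumes")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


@dataclass
class AnalysisResult:
    """In-memory results of the core analysis."""

    graph: GroupGraph
    clustering: LinkCommunities
    region_table: pd.DataFrame
    subject_table: pd.DataFrame


def analyze_cohort(
    subjects: list[SubjectTimeSeries],
    sparsity: float | None = 0.10,
    n_edges: int | None = None,
    method: str = "tanimoto",
    self_weight: bool = False,
    window: int = DEFAULT_WINDOW,
    n_perm: int = 0,
    min_second: int = 2,
    seed: int | None = None,
) -> AnalysisResult:
    """Run graph construction, link clustering and the VNP analysis.

    ``n_perm = 0`` skips the per-region permutation test (the VNP point
    estimates do not depend on it).
    """
    graph = build_group_graph(subjects, sparsity=sparsity, n_edges=n_edges)
    lc = LinkCommunities(
        method=method, self_weight=self_weight, min_second=min_second
    ).fit(graph)
    changes = change_tensor(subjects, graph.edges, window=window)
    region_table, subject_table = whole_brain_vnp(
        changes,
        graph,
        lc.partition_,
        lc.memberships_,
        subject_ids=[ts.subject_id for ts in subjects],
        n_perm=n_perm,
        seed=seed,
    )
    return AnalysisResult(
        graph=graph,
        clustering=lc,
        region_table=region_table,
        subject_table=subject_table,
    )


@dataclass
class RunManifest:
    """Record of a completed pipeline run."""

    config: dict
    version: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig,
    association_spec: list[AssociationSpec] | None = None,
) -> RunManifest:
    """Execute all stages and write every artifact to ``output_dir``."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(), version=__version__, seed=config.seed
    )
    ss = np.random.SeedSequence(config.seed)
    perm_seed, rel_seed = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2)
    )

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest.timings[name] = time.perf_counter() - t0
            return result
        return wrap

    if config.timeseries_manifest is None:
        raise ValueError("configuration has no timeseries manifest")
    subjects = stage("load")(
        lambda: hio.read_timeseries_manifest(config.timeseries_manifest)
    )
    result = stage("analyze")(
        lambda: analyze_cohort(
            subjects,
            sparsity=config.sparsity,
            n_edges=config.n_edges,
            method=config.method,
            self_weight=config.self_weight,
            window=config.window,
            n_perm=config.n_perm,
            min_second=config.min_second,
            seed=perm_seed,
        )
    )

    def write_all():
        hio.write_edge_list(result.graph, out / "edges.tsv")
        hio.write_partition(
            result.graph, result.clustering.partition_, out / "partition.tsv"
        )
        hio.write_memberships(result.clustering.memberships_, out / "memberships.csv")
        hio.write_dendrogram(result.clustering.linkage_, out / "dendrogram.tsv")
        result.region_table.to_csv(out / "vnp_regions.csv", index=False)
        result.subject_table.to_csv(out / "vnp_subjects.csv", index=False)
        manifest.outputs.update(
            {
                "edges": str(out / "edges.tsv"),
                "partition": str(out / "partition.tsv"),
                "memberships": str(out / "memberships.csv"),
                "dendrogram": str(out / "dendrogram.tsv"),
                "vnp_regions": str(out / "vnp_regions.csv"),
                "vnp_subjects": str(out / "vnp_subjects.csv"),
            }
        )

    stage("write")(write_all)

    if config.behavior_table is not None:
        def associate():
            behavior = hio.read_behavior(config.behavior_table)
            spec = association_spec or default_association_spec()
            table = run_association_suite(result.subject_table, behavior, spec)
            table.to_csv(out / "associations.csv", index=False)
            manifest.outputs["associations"] = str(out / "associations.csv")
        stage("associate")(associate)

    def reliability():
        if len(subjects) >= 4:
            r, p = split_half_reliability(
                subjects,
                sparsity=config.sparsity,
                n_edges=config.n_edges,
                method=config.method,
                self_weight=config.self_weight,
                seed=rel_seed,
            )
            pd.DataFrame(
                [{"cophenetic_r": r, "mantel_p": p}]
            ).to_csv(out / "reliability.csv", index=False)
            manifest.outputs["reliability"] = str(out / "reliability.csv")
    stage("reliability")(reliability)

    hio.write_yaml(
        {
            "config": manifest.config,
            "version": manifest.version,
            "seed": manifest.seed,
            "outputs": manifest.outputs,
            "timings": manifest.timings,
        },
        out / "run_manifest.yaml",
    )
    for path in manifest.outputs.values():
        assert Path(path).exists()
    return manifest
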