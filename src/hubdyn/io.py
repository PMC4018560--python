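"""Readers and writers for the pipeline's tabular formats.

All tabular outputs are UTF-8 comma- or tab-delimited text with 0-based
vertex ids. Time series are headerless TSV (T rows x P columns), one file
per subject, indexed by a manifest CSV; graph edge lists, link partitions,
membership tables and association results are delimited text with headers;
configurations are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .graphs import GroupGraph, SubjectTimeSeries
from .linkcluster import LinkPartition, MembershipMap, _make_partition


# ---------------------------------------------------------------------------
# time series


def write_timeseries(ts: SubjectTimeSeries, path: str | Path) -> None:
    # %.17g preserves float64 exactly, keeping write/read roundtrips
    # bit-identical
    np.savetxt(path, ts.data, delimiter="\t", fmt="%.17g")


def read_timeseries(
    path: str | Path, subject_id: str | None = None, tr: float = 0.645
) -> SubjectTimeSeries:
    path = Path(path)
    try:
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return SubjectTimeSeries(
        subject_id=subject_id or path.stem, data=data, tr=tr
    )


def write_cohort(
    subjects: list[SubjectTimeSeries], out_dir: str | Path
) -> Path:
    """Write one TSV per subject plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in subjects:
        fname = f"{ts.subject_id}_timeseries.tsv"
        write_timeseries(ts, out_dir / fname)
        rows.append({"subject_id": ts.subject_id, "path": fname, "tr": ts.tr})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_timeseries_manifest(path: str | Path) -> list[SubjectTimeSeries]:
    """Load all subjects listed in a manifest CSV, in manifest order.

    Enforces a consistent parcel count across subjects and reports the
    offending files otherwise.
    """
    path = Path(path)
    manifest = pd.read_csv(path)
    if not {"subject_id", "path"} <= set(manifest.columns):
        raise ValueError(f"{path}: manifest needs subject_id and path columns")
    subjects = []
    for row in manifest.itertuples(index=False):
        ts_path = Path(row.path)
        if not ts_path.is_absolute():
            ts_path = path.parent / ts_path
        tr = float(getattr(row, "tr", 0.645))
        subjects.append(read_timeseries(ts_path, str(row.subject_id), tr))
    shapes = {ts.n_parcels for ts in subjects}
    if len(shapes) > 1:
        offenders = {
            ts.subject_id: ts.n_parcels
            for ts in subjects
            if ts.n_parcels != subjects[0].n_parcels
        }
        raise ValueError(
            f"inconsistent parcel counts (expected {subjects[0].n_parcels}): "
            f"{offenders}"
        )
    return subjects


# ---------------------------------------------------------------------------
# graphs, partitions, dendrograms


def write_edge_list(graph: GroupGraph, path: str | Path) -> None:
    pd.DataFrame(
        {
            "i": graph.edges[:, 0],
            "j": graph.edges[:, 1],
            "weight": graph.weights,
        }
    ).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path, n_vertices: int | None = None) -> GroupGraph:
    df = pd.read_csv(path, sep="\t")
    edges = df[["i", "j"]].to_numpy(dtype=np.intp)
    if n_vertices is None:
        n_vertices = int(edges.max()) + 1 if len(edges) else 0
    return GroupGraph(
        n_vertices=n_vertices,
        edges=edges,
        weights=df["weight"].to_numpy(dtype=float),
    )


def write_partition(
    graph: GroupGraph, partition: LinkPartition, path: str | Path
) -> None:
    pd.DataFrame(
        {
            "i": graph.edges[:, 0],
            "j": graph.edges[:, 1],
            "cluster_id": partition.labels,
        }
    ).to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path, graph: GroupGraph) -> LinkPartition:
    df = pd.read_csv(path, sep="\t")
    edges = df[["i", "j"]].to_numpy(dtype=np.intp)
    if len(edges) != graph.n_edges or not np.array_equal(edges, graph.edges):
        raise ValueError(f"{path}: partition edges do not match the graph")
    return _make_partition(df["cluster_id"].to_numpy(), graph.edges)


def write_memberships(memberships: MembershipMap, path: str | Path) -> None:
    memberships.table.to_csv(path, index=False)


def write_dendrogram(dendrogram: np.ndarray, path: str | Path) -> None:
    """Merge-list text format: one row per merge.

    Columns ``left,right,height,size``: the ids of the merged subtrees
    (leaves are 0..M-1, merge ``k`` creates id ``M+k``), the merge height
    ``1 - S``, and the number of leaves below the new node.
    """
    pd.DataFrame(
        dendrogram, columns=["left", "right", "height", "size"]
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_dendrogram(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# behavior and configuration


def write_behavior(behavior: pd.DataFrame, path: str | Path) -> None:
    behavior.to_csv(path, index=False)


def read_behavior(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
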