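"""Readers, writers and the end-to-end report pipeline.

Dialects are pinned for bit-exact regression testing: comma-separated
matrices and result tables, tab-separated metadata and edge lists, UTF-8,
LF line endings, ``.`` decimal separator, floating values printed at
fixed 9-digit precision, missing metrics as the literal token ``NA``.
Logging goes to standard error; outputs go to files only.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import coalteration as _coalt
from . import embedding as _embed
from . import metrics as _metrics
from .core import (
    CANONICAL_NETWORKS,
    DEFAULT_PRIORITY,
    Confidence,
    Design,
    FingerprintMatrix,
    Hemisphere,
    MatrixFormatError,
    Method,
    NetworkScheme,
    RegionRecord,
    StudyRecord,
    Tissue,
    UnknownIdentifierError,
    validate_matrix,
)

__all__ = [
    "NA_TOKEN",
    "FLOAT_FORMAT",
    "RunConfig",
    "read_fingerprint",
    "write_fingerprint",
    "write_metrics_csv",
    "write_edge_list",
    "write_graphml",
    "write_eigen_summary",
    "write_scores",
    "write_merge_table",
    "run_report",
    "REPORT_FILES",
]

logger = logging.getLogger("snfkit")

NA_TOKEN = "NA"
FLOAT_FORMAT = "%.9f"

_HEMI_CODE = {"L": Hemisphere.LEFT, "R": Hemisphere.RIGHT, "B": Hemisphere.BILATERAL}

REPORT_FILES = (
    "metrics.csv", "edges.tsv", "graph.graphml", "eigen.csv",
    "scores.csv", "dendrogram.nwk", "merges.csv", "run_summary.json",
)


def _fmt(value: float) -> str:
    return NA_TOKEN if value is None or (isinstance(value, float) and math.isnan(value)) \
        else FLOAT_FORMAT % value


def _read_table(path: Path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MatrixFormatError(f"{path}: missing column(s) {missing}")


def read_fingerprint(
    matrix_path: str | Path,
    roi_path: str | Path,
    study_path: str | Path,
    network_ids: Sequence[str] | None = None,
    priority: Sequence[str] | None = None,
) -> tuple[FingerprintMatrix, NetworkScheme]:
    """Load and cross-reference the matrix CSV and the two metadata TSVs.

    Every matrix row must have an ROI metadata record and every column a
    study record (missing ids raise :class:`UnknownIdentifierError`);
    non-ternary cells and duplicate ids raise :class:`MatrixFormatError`
    with their location.  The returned scheme uses the canonical network
    vocabulary and priority when the files reference only canonical
    networks, otherwise the networks in order of first appearance.
    """
    matrix_path, roi_path, study_path = Path(matrix_path), Path(roi_path), Path(study_path)

    roi_df = _read_table(roi_path, "\t")
    _require_columns(roi_df, ["roi_id", "label", "hemisphere", "tissue", "networks"], roi_path)
    regions_by_id: dict[str, RegionRecord] = {}
    for _, row in roi_df.iterrows():
        roi_id = row["roi_id"].strip()
        if roi_id in regions_by_id:
            raise MatrixFormatError(f"{roi_path}: duplicate roi_id {roi_id!r}")
        hemi = row["hemisphere"].strip()
        if hemi not in _HEMI_CODE:
            raise MatrixFormatError(
                f"{roi_path}: roi {roi_id!r}: hemisphere must be L, R or B, got {hemi!r}")
        networks = tuple(k for k in (s.strip() for s in row["networks"].split(";")) if k)
        try:
            regions_by_id[roi_id] = RegionRecord(
                roi_id=roi_id, label=row["label"], hemisphere=_HEMI_CODE[hemi],
                tissue=Tissue(row["tissue"].strip()), networks=networks)
        except ValueError as exc:
            raise MatrixFormatError(f"{roi_path}: roi {roi_id!r}: {exc}") from exc

    study_df = _read_table(study_path, "\t")
    _require_columns(study_df, ["study_id", "citation", "method", "design", "confidence"],
                     study_path)
    studies_by_id: dict[str, StudyRecord] = {}
    for _, row in study_df.iterrows():
        study_id = row["study_id"].strip()
        if study_id in studies_by_id:
            raise MatrixFormatError(f"{study_path}: duplicate study_id {study_id!r}")
        try:
            studies_by_id[study_id] = StudyRecord(
                study_id=study_id, citation=row["citation"],
                method=Method(row["method"].strip()),
                design=Design(row["design"].strip()),
                confidence=Confidence(row["confidence"].strip()))
        except ValueError as exc:
            raise MatrixFormatError(f"{study_path}: study {study_id!r}: {exc}") from exc

    mat_df = _read_table(matrix_path, ",")
    if not mat_df.columns.size or mat_df.columns[0] != "roi_id":
        raise MatrixFormatError(f"{matrix_path}: first column header must be 'roi_id'")
    study_ids = [c for c in mat_df.columns[1:]]
    if len(set(study_ids)) != len(study_ids):
        raise MatrixFormatError(f"{matrix_path}: duplicate study column headers")
    roi_ids = [r.strip() for r in mat_df["roi_id"]]
    if len(set(roi_ids)) != len(roi_ids):
        raise MatrixFormatError(f"{matrix_path}: duplicate roi_id rows")

    entries = np.zeros((len(roi_ids), len(study_ids)), dtype=np.int8)
    for i, (_, row) in enumerate(mat_df.iterrows()):
        for j, sid in enumerate(study_ids):
            cell = str(row[sid]).strip()
            if cell not in {"-1", "0", "1", "+1"}:
                raise MatrixFormatError(
                    f"{matrix_path}: line {i + 2}, column {sid!r}: "
                    f"cell {cell!r} is not in {{-1, 0, 1}}")
            entries[i, j] = int(cell)

    regions = []
    for roi_id in roi_ids:
        if roi_id not in regions_by_id:
            raise UnknownIdentifierError(
                f"matrix row {roi_id!r} has no ROI metadata in {roi_path}")
        regions.append(regions_by_id[roi_id])
    studies = []
    for sid in study_ids:
        if sid not in studies_by_id:
            raise UnknownIdentifierError(
                f"matrix column {sid!r} has no study metadata in {study_path}")
        studies.append(studies_by_id[sid])

    m = FingerprintMatrix(tuple(regions), tuple(studies), entries)
    referenced: list[str] = []
    for r in regions:
        for k in r.networks:
            if k not in referenced:
                referenced.append(k)
    if network_ids is None:
        if set(referenced) <= set(CANONICAL_NETWORKS):
            network_ids, priority = CANONICAL_NETWORKS, DEFAULT_PRIORITY
        else:
            network_ids, priority = tuple(referenced), tuple(referenced)
    scheme = NetworkScheme.from_regions(
        regions, network_ids=network_ids,
        priority=priority if priority is not None else network_ids)
    return m, scheme


def write_fingerprint(
    m: FingerprintMatrix,
    matrix_path: str | Path,
    roi_path: str | Path,
    study_path: str | Path,
) -> None:
    """Write the matrix CSV and the ROI / study metadata TSVs."""
    with open(matrix_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("roi_id," + ",".join(m.study_ids) + "\n")
        for region, row in zip(m.regions, m.entries):
            fh.write(region.roi_id + "," + ",".join(str(int(v)) for v in row) + "\n")
    with open(roi_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("roi_id\tlabel\themisphere\ttissue\tnetworks\n")
        for r in m.regions:
            fh.write("\t".join([
                r.roi_id, r.label, r.hemisphere.value, r.tissue.value,
                ";".join(r.networks)]) + "\n")
    with open(study_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("study_id\tcitation\tmethod\tdesign\tconfidence\n")
        for s in m.studies:
            fh.write("\t".join([
                s.study_id, s.citation, s.method.value, s.design.value,
                s.confidence.value]) + "\n")


def write_metrics_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Per-network metrics with NA for undefined indices."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("network,region_count,load,distinct_regions,"
                 "per_region_index,mean_direction,rank\n")
        for _, row in table.iterrows():
            fh.write(",".join([
                row["network"], str(int(row["region_count"])), str(int(row["load"])),
                str(int(row["distinct_regions"])), _fmt(row["per_region_index"]),
                _fmt(row["mean_direction"]), str(int(row["rank"]))]) + "\n")


def write_edge_list(g: "_coalt.CoalterationGraph", path: str | Path) -> None:
    """TSV edge list ``source, target, weight`` sorted for determinism."""
    edges = sorted((min(u, v), max(u, v), int(d["weight"]))
                   for u, v, d in g.graph.edges(data=True))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, w in edges:
            fh.write(f"{u}\t{v}\t{w}\n")


def write_graphml(g: "_coalt.CoalterationGraph", path: str | Path) -> None:
    """GraphML with node attributes label, dominant_network, strength."""
    out = nx.Graph()
    strength = _coalt.node_strength(g)
    for v in sorted(g.graph.nodes):
        data = g.graph.nodes[v]
        out.add_node(v, label=data.get("label", v),
                     dominant_network=data.get("dominant_network", ""),
                     strength=int(strength[v]))
    for u, v, d in sorted(g.graph.edges(data=True)):
        out.add_edge(u, v, weight=int(d["weight"]))
    nx.write_graphml(out, str(path))


def write_eigen_summary(emb: "_embed.EmbeddingResult", path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("component,eigenvalue,explained_variance_ratio\n")
        for i, (lam, evr) in enumerate(
                zip(emb.eigenvalues, emb.explained_variance_ratio), start=1):
            fh.write(f"{i},{_fmt(float(lam))},{_fmt(float(evr))}\n")


def write_scores(emb: "_embed.EmbeddingResult", path: str | Path) -> None:
    n_comp = emb.scores.shape[1]
    header = ["roi_id"] + [f"pc{i + 1}" for i in range(n_comp)] + ["dominant_network"]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(header) + "\n")
        for roi, row, net in zip(emb.roi_ids, emb.scores, emb.networks):
            fh.write(",".join([roi] + [_fmt(float(v)) for v in row] + [net]) + "\n")


def write_merge_table(c: "_embed.ClusteringResult", path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("step,member_a,member_b,height,size\n")
        for step, (a, b, h, size) in enumerate(c.merge_tree, start=1):
            fh.write(f"{step},{a},{b},{_fmt(h)},{size}\n")


@dataclass
class RunConfig:
    """Configuration for the end-to-end report pipeline."""

    matrix_path: Path
    roi_path: Path
    study_path: Path
    out_dir: Path
    tau: int = _coalt.DEFAULT_TAU
    sweep_taus: tuple[int, ...] = (1, 2, 3)
    n_components: int = 2
    n_clusters: int = 7  # number of canonical networks
    use_centered: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.n_components < 1:
            raise ValueError(f"n_components must be >= 1, got {self.n_components}")
        if self.n_clusters < 2:
            raise ValueError(f"n_clusters must be >= 2, got {self.n_clusters}")
        for name in ("matrix_path", "roi_path", "study_path", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))


def _stage(name: str, started: float) -> None:
    logger.info("stage %-12s done in %.3f s", name, time.perf_counter() - started)


def run_report(config: RunConfig) -> dict:
    """Run metrics -> co-alteration (with sweep) -> PCA -> clustering.

    Writes the eight report files to ``config.out_dir`` and returns the
    run summary dict (also written as ``run_summary.json``).  On any
    stage failure the partially written outputs of this run are removed
    and the error re-raised with the stage name.
    """
    from . import __version__

    logging.basicConfig(level=config.log_level, stream=None)
    logger.setLevel(config.log_level)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _target(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    stage = "read"
    try:
        t0 = time.perf_counter()
        m, scheme = read_fingerprint(config.matrix_path, config.roi_path, config.study_path)
        issues = validate_matrix(m)
        errors = [i for i in issues if i.severity == "ERROR"]
        if errors:
            raise MatrixFormatError(
                "matrix failed validation: " + "; ".join(i.message for i in errors))
        _stage(stage, t0)

        stage = "metrics"
        t0 = time.perf_counter()
        table = _metrics.metrics_table(m, scheme)
        write_metrics_csv(table, _target("metrics.csv"))
        _stage(stage, t0)

        stage = "coalteration"
        t0 = time.perf_counter()
        c = _coalt.coalteration_matrix(m)
        g = _coalt.build_graph(c, tau=config.tau, scheme=scheme)
        sweep = _coalt.threshold_sweep(c, taus=config.sweep_taus, scheme=scheme)
        write_edge_list(g, _target("edges.tsv"))
        write_graphml(g, _target("graph.graphml"))
        _stage(stage, t0)

        stage = "pca"
        t0 = time.perf_counter()
        emb = _embed.embed(m, scheme, n_components=config.n_components)
        write_eigen_summary(emb, _target("eigen.csv"))
        write_scores(emb, _target("scores.csv"))
        _stage(stage, t0)

        stage = "clustering"
        t0 = time.perf_counter()
        clust = _embed.ward_dendrogram(m, use_centered=config.use_centered)
        with open(_target("dendrogram.nwk"), "w", encoding="utf-8", newline="\n") as fh:
            fh.write(_embed.export_newick(clust) + "\n")
        write_merge_table(clust, _target("merges.csv"))
        k = min(config.n_clusters, m.n_regions)
        ari = _embed.cluster_network_agreement(clust, scheme, k) if k >= 2 else math.nan
        _stage(stage, t0)

        stage = "summary"
        t0 = time.perf_counter()
        modules = _coalt.connected_modules(g)
        summary = {
            "package": "snfkit",
            "version": __version__,
            "config": {
                "matrix_path": str(config.matrix_path),
                "roi_path": str(config.roi_path),
                "study_path": str(config.study_path),
                "tau": config.tau,
                "sweep_taus": list(config.sweep_taus),
                "n_components": config.n_components,
                "n_clusters": config.n_clusters,
                "use_centered": config.use_centered,
                "seed": config.seed,
            },
            "n_regions": m.n_regions,
            "n_studies": m.n_studies,
            "total_abnormal_entries": int(np.abs(m.entries).sum()),
            "validation_warnings": [i.message for i in issues],
            "network_metrics": {
                row["network"]: {
                    "region_count": int(row["region_count"]),
                    "load": int(row["load"]),
                    "distinct_regions": int(row["distinct_regions"]),
                    "per_region_index": None if math.isnan(row["per_region_index"])
                    else round(row["per_region_index"], 9),
                    "mean_direction": None if math.isnan(row["mean_direction"])
                    else round(row["mean_direction"], 9),
                    "rank": int(row["rank"]),
                }
                for _, row in table.iterrows()
            },
            "graph": {
                "tau": config.tau,
                "abnormal_only_nodes": True,
                "n_nodes": g.graph.number_of_nodes(),
                "n_edges": g.graph.number_of_edges(),
                "density": round(g.density, 9),
                "largest_module": sorted(modules[0]) if modules else [],
            },
            "sweep": {
                "taus": list(sweep.taus),
                "edge_counts": list(sweep.edge_counts),
                "densities": [round(d, 9) for d in sweep.densities],
            },
            "pca": {
                "eigenvalues": [round(float(v), 9) for v in emb.eigenvalues],
                "explained_variance_ratio": [
                    round(float(v), 9) for v in emb.explained_variance_ratio],
            },
            "clustering": {
                "n_clusters": k,
                "adjusted_rand_vs_networks": None if math.isnan(ari) else round(ari, 9),
            },
        }
        with open(_target("run_summary.json"), "w", encoding="utf-8", newline="\n") as fh:
            json.dump(summary, fh, indent=2, sort_keys=False)
            fh.write("\n")
        _stage(stage, t0)
        return summary
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"report stage {stage!r} failed: {exc}") from exc
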