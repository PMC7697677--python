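"""End-to-end orchestration: QC → normalize → cluster → markers → screen.

`run_pipeline` works on in-memory objects and returns a `RunResult`;
`run_pipeline_files` wraps it with file IO and writes every stage output
plus a `RunManifest` (config snapshot, input hashes, seed, timings,
output paths, package version) sufficient to re-run identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cell_qc import QCReport, compute_qc_profiles, filter_cells
from .cluster_markers import (
    ClusterAssignment,
    NormalizedMatrix,
    embed_and_cluster,
    find_all_markers,
    gene_correlation,
    label_clusters,
    normalize,
)
from .io_formats import (
    CountMatrix,
    GeneSet,
    LocalizationTable,
    OrganExpressionMatrix,
    OrthologMap,
    RunConfig,
    write_funnel_report,
)
from .marker_screen import FunnelResult, run_funnel

logger = logging.getLogger(__name__)

__all__ = ["RunResult", "RunManifest", "run_pipeline", "run_pipeline_files"]


@dataclass
class RunResult:
    config: RunConfig
    kept_cells: list[str]
    qc_report: QCReport
    normalized: NormalizedMatrix
    assignment: ClusterAssignment
    marker_tables: dict[int, pd.DataFrame]
    target_cluster: int
    funnel: FunnelResult
    correlations: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class RunManifest:
    version: str
    seed: int
    config: dict
    input_hashes: dict[str, str]
    outputs: dict[str, str]
    timings_s: dict[str, float]

    def write(self, path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")
        tmp.replace(path)  # atomic at run end

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _target_cluster(labels: dict[int, str], target_label: str = "AT1") -> int:
    """Cluster id carrying the target label (bare or disambiguated)."""
    for k, lab in sorted(labels.items()):
        if lab == target_label or lab.startswith(f"{target_label}-"):
            return k
    raise ValueError(f"no cluster labelled {target_label!r}; labels: {labels}")


def run_pipeline(
    cm: CountMatrix,
    external_sets: list[GeneSet],
    foreign_set: GeneSet,
    orthologs: OrthologMap,
    organ_matrix: OrganExpressionMatrix,
    localization: LocalizationTable,
    config: RunConfig,
    target_label: str = "AT1",
    correlation_pairs: tuple[tuple[str, str], ...] = (),
) -> RunResult:
    """Run QC, clustering, marker detection and the funnel in order.

    ``correlation_pairs`` optionally requests reporter–gene Spearman
    correlations over the epithelial subset (all clusters not labelled
    fibroblast).
    """
    profiles = compute_qc_profiles(
        cm, config.mito_prefix,
        exclude_genes=() if config.count_transgene_in_qc else config.exclude_genes,
    )
    kept, qc_report = filter_cells(profiles, config)
    logger.info("QC: kept %d / %d cells", len(kept), cm.n_cells)
    if not kept:
        raise RuntimeError("QC removed every cell; nothing to cluster")

    norm = normalize(cm.subset_cells(kept), config.scale)
    assignment, _ = embed_and_cluster(norm, config)
    tables = find_all_markers(
        norm, assignment, exclude_genes=config.exclude_genes,
        adjust_method=config.adjust_method,
    )
    assignment.labels = label_clusters(tables)
    target = _target_cluster(assignment.labels, target_label)

    funnel = run_funnel(
        tables[target], external_sets, foreign_set, orthologs,
        organ_matrix, localization, config,
    )

    correlations = {}
    if correlation_pairs:
        epithelial = [
            c for c in norm.cells
            if not assignment.label_of(assignment.cluster_of[c]).startswith("fibroblast")
        ]
        for a, b in correlation_pairs:
            if norm.has_gene(a) and norm.has_gene(b):
                res = gene_correlation(norm, a, b, epithelial)
                correlations[f"{a}~{b}"] = (res.rho, res.p_value)

    return RunResult(
        config=config,
        kept_cells=kept,
        qc_report=qc_report,
        normalized=norm,
        assignment=assignment,
        marker_tables=tables,
        target_cluster=target,
        funnel=funnel,
        correlations=correlations,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline_files(
    config: RunConfig,
    outdir,
    target_label: str = "AT1",
    correlation_pairs: tuple[tuple[str, str], ...] = (),
) -> RunManifest:
    """File-based run: reads the inputs named in ``config.paths``, writes
    every stage output under ``outdir`` and a manifest at the end.

    Required ``config.paths`` keys: ``matrix`` (plus ``genes``/``cells``
    for MatrixMarket input), ``external`` (list), ``foreign``,
    ``orthologs``, ``organ_matrix``, ``organ_samples``, ``localization``.
    Missing paths fail before any compute.
    """
    from .io_formats import read_count_matrix, read_gene_set

    paths = dict(config.paths)
    required = ["matrix", "external", "foreign", "orthologs",
                "organ_matrix", "organ_samples", "localization"]
    missing = [k for k in required if k not in paths]
    if missing:
        raise ValueError(f"config.paths missing keys: {missing}")
    flat = []
    for k in required:
        v = paths[k]
        flat.extend(v if isinstance(v, list) else [v])
    for k in ("genes", "cells"):
        if k in paths:
            flat.append(paths[k])
    absent = [p for p in flat if not Path(p).exists()]
    if absent:
        raise FileNotFoundError(f"missing input files: {absent}")

    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    cm = read_count_matrix(paths["matrix"], paths.get("genes"), paths.get("cells"))
    externals = [read_gene_set(p, species="mouse")
                 for p in (paths["external"] if isinstance(paths["external"], list)
                           else [paths["external"]])]
    foreign = read_gene_set(paths["foreign"], species="human")
    orthologs = OrthologMap.from_tsv(paths["orthologs"])
    organ = OrganExpressionMatrix.read(paths["organ_matrix"], paths["organ_samples"])
    localization = LocalizationTable.from_tsv(paths["localization"])
    timings["read_inputs"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    result = run_pipeline(cm, externals, foreign, orthologs, organ, localization,
                          config, target_label, correlation_pairs)
    timings["pipeline"] = time.perf_counter() - t0

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = {}

    t0 = time.perf_counter()
    qc_path = outdir / "qc_table.tsv"
    result.qc_report.to_tsv(qc_path)
    outputs["qc_table"] = str(qc_path)

    clusters_path = outdir / "clusters.tsv"
    result.assignment.to_frame().to_csv(clusters_path, sep="\t", index=False)
    outputs["clusters"] = str(clusters_path)

    markers_path = outdir / "markers.tsv"
    pd.concat(result.marker_tables.values()).to_csv(markers_path, sep="\t", index=False)
    outputs["markers"] = str(markers_path)

    funnel_path = outdir / "funnel_report.json"
    write_funnel_report(result.funnel, funnel_path)
    outputs["funnel_report"] = str(funnel_path)

    if result.correlations:
        corr_path = outdir / "correlations.tsv"
        with open(corr_path, "w") as fh:
            fh.write("pair\trho\tp_value\n")
            for pair, (rho, p) in sorted(result.correlations.items()):
                fh.write(f"{pair}\t{rho:.6g}\t{p:.6g}\n")
        outputs["correlations"] = str(corr_path)
    timings["write_outputs"] = time.perf_counter() - t0

    manifest = RunManifest(
        version=__version__,
        seed=config.seed,
        config=config.to_dict(),
        input_hashes={str(p): _sha256(Path(p)) for p in flat},
        outputs=outputs,
        timings_s={k: round(v, 6) for k, v in timings.items()},
    )
    manifest.write(outdir / "manifest.json")
    return manifest
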