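"""Normalization, graph clustering, cluster markers and gene correlation.

The route is the standard single-cell recipe, assembled natively:
counts-per-million + log1p normalization; highly-variable-gene selection by
dispersion; PCA; a k-nearest-neighbour graph in PC space; Leiden community
detection at a configured resolution with a fixed seed.  Cluster markers
come from a two-sided Wilcoxon rank-sum test of in-cluster vs all other
cells with Benjamini–Hochberg adjustment per cluster contrast, and clusters
are labelled post hoc from canonical cell-type markers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from . import stats
from .io_formats import CountMatrix, GeneSet, RunConfig, canonical_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "ClusterAssignment",
    "normalize",
    "embed_and_cluster",
    "find_markers",
    "find_all_markers",
    "top_n_markers",
    "label_clusters",
    "gene_correlation",
    "CANONICAL_CELL_TYPE_MARKERS",
]

#: canonical lung cell-type markers used for post-hoc cluster labelling
CANONICAL_CELL_TYPE_MARKERS: dict[str, tuple[str, ...]] = {
    "club": ("Scgb1a1",),
    "basal": ("Krt5",),
    "AT2": ("Sftpc",),
    "AT1": ("Ager", "Hopx", "Pdpn", "Cav1", "Cav2", "Igfbp2", "Gramd2"),
    "ciliated": ("Foxj1",),
    "fibroblast": ("Vim",),
}

MARKER_TABLE_COLUMNS = [
    "gene", "cluster", "log2_fold_change", "p_value", "adjusted_p",
    "in_cluster_mean", "out_cluster_mean", "rank",
]


@dataclass
class NormalizedMatrix:
    """log1p(CPM)-normalized expression on the same gene × cell axes.

    ``library_sizes`` records the raw per-cell totals so the raw column
    sums remain recoverable; ``cpm()`` returns the linear-scale values.
    """

    genes: list[str]
    cells: list[str]
    values: np.ndarray  # gene x cell, log1p(count / libsize * scale)
    library_sizes: np.ndarray
    scale: float

    def __post_init__(self):
        self._gene_index = {canonical_symbol(g): i for i, g in enumerate(self.genes)}

    def gene_row(self, symbol: str) -> int:
        return self._gene_index[canonical_symbol(symbol)]

    def has_gene(self, symbol: str) -> bool:
        return canonical_symbol(symbol) in self._gene_index

    def cpm(self) -> np.ndarray:
        return np.expm1(self.values)


@dataclass
class ClusterAssignment:
    """cell → cluster id (contiguous from 1) plus optional post-hoc labels."""

    cluster_of: dict[str, int]
    labels: dict[int, str] = field(default_factory=dict)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.cluster_of.values()))

    def cells_in(self, cluster: int) -> list[str]:
        return [c for c, k in self.cluster_of.items() if k == cluster]

    def label_of(self, cluster: int) -> str:
        return self.labels.get(cluster, "unlabeled")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": list(self.cluster_of),
                "cluster": [self.cluster_of[c] for c in self.cluster_of],
                "label": [self.label_of(self.cluster_of[c]) for c in self.cluster_of],
            }
        )


def normalize(cm: CountMatrix, scale: float = 1e6) -> NormalizedMatrix:
    """Counts-per-million + log1p normalization between cells.

    value(g, c) = log1p(count(g, c) / libsize(c) * scale).  All-zero cells
    (normally removed by QC) are passed through as zeros with a warning.
    Doubling every count of a cell leaves its normalized vector unchanged.
    """
    counts = cm.dense().astype(float)
    libsize = counts.sum(axis=0)
    if np.any(libsize == 0):
        warnings.warn("all-zero cells passed to normalize(); left as zeros")
    safe = np.where(libsize > 0, libsize, 1.0)
    values = np.log1p(counts / safe * scale)
    return NormalizedMatrix(
        list(cm.genes), list(cm.cells), values, libsize.astype(np.int64), scale
    )


def _select_hvg(norm: NormalizedMatrix, n_hvg: int) -> np.ndarray:
    """Indices of the top ``n_hvg`` genes by dispersion (var/mean of CPM)."""
    cpm = norm.cpm()
    mean = cpm.mean(axis=1)
    var = cpm.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    order = np.argsort(-dispersion, kind="stable")
    return np.sort(order[: min(n_hvg, norm.values.shape[0])])


def embed_and_cluster(
    norm: NormalizedMatrix, config: RunConfig
) -> tuple[ClusterAssignment, np.ndarray]:
    """Cluster cells; returns the assignment and the PC embedding.

    Pipeline: top ``n_hvg`` genes by dispersion → per-gene z-scaling → PCA
    to ``n_pcs`` → kNN graph (Euclidean in PC space, undirected union of
    directed edges) → Leiden modularity communities at ``resolution`` with
    the configured seed.  Deterministic given the seed.
    """
    n_cells = len(norm.cells)
    if n_cells < config.k_neighbors + 1:
        raise ValueError(
            f"{n_cells} cells but k_neighbors={config.k_neighbors}; "
            "need at least k_neighbors + 1 cells"
        )
    hvg = _select_hvg(norm, config.n_hvg)
    x = norm.values[hvg].T  # cells x genes
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - mu) / sd

    n_pcs = min(config.n_pcs, min(x.shape) - 1) or 1
    pcs = PCA(n_components=n_pcs, svd_solver="full", random_state=config.seed).fit_transform(x)

    # degenerate input: indistinguishable cells form a single community
    if np.allclose(pcs, pcs[0]):
        return ClusterAssignment({cell: 1 for cell in norm.cells}), pcs

    nn = NearestNeighbors(n_neighbors=config.k_neighbors + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = set()
    for i, row in enumerate(idx):
        for j in row[1:]:  # drop self
            edges.add((min(i, int(j)), max(i, int(j))))
    graph = igraph.Graph(n=n_cells, edges=sorted(edges))
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=config.resolution,
        seed=config.seed,
        n_iterations=-1,
    )
    membership = np.array(partition.membership)
    # contiguous ids from 1, ordered by decreasing cluster size (ties: first cell)
    sizes = pd.Series(membership).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index, start=1)}
    assignment = ClusterAssignment(
        {cell: remap[m] for cell, m in zip(norm.cells, membership)}
    )
    logger.info("clustered %d cells into %d communities", n_cells, len(remap))
    return assignment, pcs


def find_markers(
    norm: NormalizedMatrix,
    assignment: ClusterAssignment,
    cluster: int,
    exclude_genes: tuple[str, ...] = (),
    adjust_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Marker statistics for one cluster against all other cells.

    Per gene: two-sided Wilcoxon rank-sum of in-cluster vs out-cluster
    normalized values (exact for combined n <= 20, tie-corrected normal
    approximation otherwise); log2 fold change on the CPM scale with
    pseudocount 1; Benjamini–Hochberg adjustment across the genes of this
    contrast.  Rank is a total order: ascending adjusted p, then descending
    fold change, then symbol.
    """
    in_mask = np.array([assignment.cluster_of[c] == cluster for c in norm.cells])
    if not in_mask.any() or in_mask.all():
        raise ValueError(f"cluster {cluster}: in-group and out-group must both be non-empty")
    excluded = {canonical_symbol(g) for g in exclude_genes}
    cpm = norm.cpm()

    rows = []
    for gi, gene in enumerate(norm.genes):
        if canonical_symbol(gene) in excluded:
            continue
        vals = norm.values[gi]
        _, p = stats.rank_sum_test(vals[in_mask], vals[~in_mask])
        in_mean = float(cpm[gi, in_mask].mean())
        out_mean = float(cpm[gi, ~in_mask].mean())
        lfc = float(np.log2((in_mean + 1.0) / (out_mean + 1.0)))
        rows.append((gene, cluster, lfc, p, in_mean, out_mean))

    table = pd.DataFrame(
        rows, columns=["gene", "cluster", "log2_fold_change", "p_value",
                       "in_cluster_mean", "out_cluster_mean"]
    )
    if adjust_method == "fdr_bh":
        table["adjusted_p"] = stats.benjamini_hochberg(table["p_value"].to_numpy())
    elif adjust_method == "bonferroni":
        table["adjusted_p"] = np.minimum(table["p_value"].to_numpy() * len(table), 1.0)
    else:
        raise ValueError(f"unknown adjust_method {adjust_method!r}")
    table["_key"] = table["gene"].map(canonical_symbol)
    table = table.sort_values(
        ["adjusted_p", "log2_fold_change", "_key"],
        ascending=[True, False, True],
        kind="stable",
    ).drop(columns="_key")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)[MARKER_TABLE_COLUMNS]


def find_all_markers(
    norm: NormalizedMatrix,
    assignment: ClusterAssignment,
    exclude_genes: tuple[str, ...] = (),
    adjust_method: str = "fdr_bh",
) -> dict[int, pd.DataFrame]:
    """Marker table for every cluster; clusters of size n or 0-complement skipped."""
    tables = {}
    for k in assignment.cluster_ids:
        try:
            tables[k] = find_markers(norm, assignment, k, exclude_genes, adjust_method)
        except ValueError:
            logger.warning("cluster %d skipped: degenerate contrast", k)
    return tables


def top_n_markers(table: pd.DataFrame, n: int, name: str = "top_markers",
                  species: str = "mouse") -> GeneSet:
    """First ``n`` positively enriched genes of a marker table as a GeneSet.

    Order is the table's rank (ascending adjusted p, then descending fold
    change, then symbol); genes with log2 fold change <= 0 are never
    candidates.  If fewer than ``n`` qualify, all are returned with a
    warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    positive = table[table["log2_fold_change"] > 0].sort_values("rank")
    if len(positive) < n:
        warnings.warn(
            f"only {len(positive)} positively enriched genes available for top-{n}"
        )
    return GeneSet(name, species, list(positive["gene"].head(n)))


def label_clusters(
    tables: dict[int, pd.DataFrame],
    canonical_map: dict[str, tuple[str, ...]] | None = None,
) -> dict[int, str]:
    """Assign a cell-type label to each cluster from canonical markers.

    Each cluster gets the label whose canonical markers have the best
    (lowest) mean rank in that cluster's marker table; markers absent from
    the table count as rank ``len(table) + 1``.  A cluster in which no
    canonical marker of the winning label is expressed (in-cluster mean 0)
    is "unlabeled".  When several clusters resolve to the same label, each
    is suffixed ``-1``, ``-2``, ... in cluster-id order.
    """
    canonical_map = canonical_map or CANONICAL_CELL_TYPE_MARKERS
    raw: dict[int, str] = {}
    for k in sorted(tables):
        table = tables[k]
        rank_of = {canonical_symbol(g): r for g, r in zip(table["gene"], table["rank"])}
        mean_of = {
            canonical_symbol(g): m
            for g, m in zip(table["gene"], table["in_cluster_mean"])
        }
        worst = len(table) + 1
        best_label, best_score = "unlabeled", float("inf")
        for label in sorted(canonical_map):
            markers = canonical_map[label]
            score = float(
                np.mean([rank_of.get(canonical_symbol(m), worst) for m in markers])
            )
            expressed = any(mean_of.get(canonical_symbol(m), 0.0) > 0 for m in markers)
            if expressed and score < best_score:
                best_label, best_score = label, score
        raw[k] = best_label

    counts = pd.Series([v for v in raw.values() if v != "unlabeled"]).value_counts()
    duplicated = set(counts[counts > 1].index) if len(counts) else set()
    labels: dict[int, str] = {}
    seen: dict[str, int] = {}
    for k in sorted(raw):
        label = raw[k]
        if label in duplicated:
            seen[label] = seen.get(label, 0) + 1
            labels[k] = f"{label}-{seen[label]}"
        else:
            labels[k] = label
    return labels


def gene_correlation(
    norm: NormalizedMatrix,
    gene_a: str,
    gene_b: str,
    cell_subset: list[str] | None = None,
) -> stats.SpearmanResult:
    """Spearman correlation between two genes over a cell subset.

    Computed on normalized values (ranks are invariant to the monotone
    CPM/log transforms).  Requires both genes present and at least three
    cells; a constant vector yields an undefined (flagged) result.
    """
    for g in (gene_a, gene_b):
        if not norm.has_gene(g):
            raise KeyError(f"gene {g!r} not in matrix")
    if cell_subset is None:
        cols = np.arange(len(norm.cells))
    else:
        pos = {c: i for i, c in enumerate(norm.cells)}
        cols = np.array([pos[c] for c in cell_subset])
    if cols.size < 3:
        raise ValueError("correlation requires at least 3 cells")
    return stats.spearman(
        norm.values[norm.gene_row(gene_a), cols],
        norm.values[norm.gene_row(gene_b), cols],
    )
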