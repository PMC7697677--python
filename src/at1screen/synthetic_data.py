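"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates a small, deeply sequenced single-cell dataset of
reporter-sorted lung epithelial cells plus the external resources the
marker screen consumes: cluster-structured negative-binomial counts with
mitochondrial-fraction variation and degraded low-quality cells; a
multi-organ bulk matrix with lung-enriched genes; external marker gene
sets with configurable dropout and decoys; an ortholog map; and a
subcellular-localization table.  Ground truth (cell clusters, marker
genes, conserved/lung-enriched/membrane flags, low-quality cells) is
returned alongside so every stage of the pipeline is testable end to end.

All generators are deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .io_formats import (
    CountMatrix,
    GeneSet,
    LocalizationTable,
    OrganExpressionMatrix,
    OrthologMap,
    canonical_symbol,
)

__all__ = ["SimSpec", "GroundTruth", "simulate_counts", "simulate_organ_matrix",
           "simulate_external_sets", "write_fixture"]

#: names of the murine mitochondrially encoded protein/rRNA genes used here
MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)

#: canonical first marker of each simulated cluster
CANONICAL_FIRST_MARKER = {
    "club": "Scgb1a1",
    "basal": "Krt5",
    "AT2": "Sftpc",
    "ciliated": "Foxj1",
    "fibroblast": "Vim",
}

#: the ten alveolar type I markers planted for the AT1 cluster
AT1_MARKER_GENES = (
    "Ager", "Rtkn2", "Gprc5a", "Gramd2", "Hopx", "Cav1",
    "Cav2", "Pdpn", "Aqp5", "Igfbp2",
)


@dataclass
class SimSpec:
    """Parameters of the synthetic study.

    Defaults are a desk-scale mirror of a ~100-cell full-length scRNA-seq
    experiment: six cell-type clusters of 20 cells, 2,000 genes, ten
    fold-8 markers per cluster, deep libraries (median 300k counts) and a
    low mitochondrial fraction, with 10 cells degraded in place to fail
    quality control.  Of the AT1 markers, six are flagged cross-species
    conserved, three of those lung-enriched, and two of those
    membrane-localized — the planted conserved-membrane set the screen
    must recover.
    """

    cluster_labels: tuple[str, ...] = ("club", "basal", "AT2", "AT1",
                                       "ciliated", "fibroblast")
    n_cells_per_cluster: int = 20
    n_genes: int = 2000
    n_markers_per_cluster: int = 10
    marker_fold_change: float = 8.0
    nb_dispersion: float = 0.3
    library_size_lognormal: tuple[float, float] = (np.log(3e5), 0.3)
    mito_frac_beta: tuple[float, float] = (5.0, 95.0)
    n_lowq_cells: int = 10
    lowq_library_size: float = 1000.0
    lowq_mito_beta: tuple[float, float] = (8.0, 12.0)
    transgene: str = "tdTomato"
    transgene_cluster: str = "AT1"
    conserved_markers: tuple[str, ...] = ("Ager", "Rtkn2", "Gprc5a",
                                          "Gramd2", "Hopx", "Cav1")
    lung_enriched_markers: tuple[str, ...] = ("Ager", "Rtkn2", "Gprc5a")
    membrane_markers: tuple[str, ...] = ("Ager", "Gprc5a")
    # organ matrix
    n_organs: int = 30  # lung + 29 others
    n_lung_samples: int = 8
    n_samples_per_organ: int = 4
    lung_fold: float = 50.0
    # external resources
    n_decoys_per_set: int = 20
    ortholog_coverage: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.marker_fold_change < 1:
            raise ValueError("marker_fold_change must be >= 1")
        if self.nb_dispersion <= 0 or self.lowq_library_size <= 0:
            raise ValueError("count parameters must be positive")
        if not (0 <= self.ortholog_coverage <= 1):
            raise ValueError("ortholog_coverage must be in [0, 1]")
        if self.n_organs < 2:
            raise ValueError("need at least two organs")
        needed = (len(self.cluster_labels) * self.n_markers_per_cluster
                  + len(MITO_GENES) + 1)
        if needed > self.n_genes:
            raise ValueError(
                f"infeasible spec: {needed} marker/mito/transgene genes exceed "
                f"n_genes={self.n_genes}"
            )
        canon = {canonical_symbol(g) for g in AT1_MARKER_GENES}
        for name, subset in (("conserved", self.conserved_markers),
                             ("lung_enriched", self.lung_enriched_markers),
                             ("membrane", self.membrane_markers)):
            if not {canonical_symbol(g) for g in subset} <= canon:
                raise ValueError(f"{name} markers must be a subset of the AT1 markers")

    @property
    def n_cells(self) -> int:
        return len(self.cluster_labels) * self.n_cells_per_cluster

    @property
    def planted_conserved_membrane(self) -> tuple[str, ...]:
        """AT1 markers flagged conserved AND lung-enriched AND membrane."""
        keys = ({canonical_symbol(g) for g in self.conserved_markers}
                & {canonical_symbol(g) for g in self.lung_enriched_markers}
                & {canonical_symbol(g) for g in self.membrane_markers})
        return tuple(g for g in AT1_MARKER_GENES if canonical_symbol(g) in keys)

    def marker_names(self) -> dict[str, list[str]]:
        """Planted marker genes per cluster label."""
        out = {}
        for label in self.cluster_labels:
            if label == "AT1":
                base = list(AT1_MARKER_GENES)
            elif label in CANONICAL_FIRST_MARKER:
                base = [CANONICAL_FIRST_MARKER[label]]
            else:
                base = []
            i = 1
            while len(base) < self.n_markers_per_cluster:
                base.append(f"{label}Mk{i}")
                i += 1
            out[label] = base[: self.n_markers_per_cluster]
        return out

    def gene_names(self) -> list[str]:
        names = list(MITO_GENES) + [self.transgene]
        for label in self.cluster_labels:
            names.extend(self.marker_names()[label])
        n_bg = self.n_genes - len(names)
        names.extend(f"Gene{i:04d}" for i in range(1, n_bg + 1))
        return names


@dataclass
class GroundTruth:
    """What was planted: the answer key for every pipeline stage."""

    cell_clusters: dict[str, str]               # cell id -> cluster label
    gene_clusters: dict[str, set[str]]          # marker gene -> clusters it marks
    gene_flags: dict[str, set[str]]             # gene -> {conserved, lung_enriched, membrane}
    lowq_cells: list[str]
    genes: list[str] = field(default_factory=list)
    transgene: str = ""

    def markers_of(self, label: str) -> list[str]:
        return [g for g, cl in self.gene_clusters.items() if label in cl]

    @property
    def conserved_membrane_markers(self) -> list[str]:
        return [g for g, f in self.gene_flags.items()
                if {"conserved", "lung_enriched", "membrane"} <= f]

    def to_json(self, path) -> None:
        payload = {
            "cell_clusters": self.cell_clusters,
            "gene_clusters": {g: sorted(c) for g, c in self.gene_clusters.items()},
            "gene_flags": {g: sorted(f) for g, f in self.gene_flags.items()},
            "lowq_cells": self.lowq_cells,
            "genes": self.genes,
            "transgene": self.transgene,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            cell_clusters=d["cell_clusters"],
            gene_clusters={g: set(c) for g, c in d["gene_clusters"].items()},
            gene_flags={g: set(f) for g, f in d["gene_flags"].items()},
            lowq_cells=d["lowq_cells"],
            genes=d["genes"],
            transgene=d["transgene"],
        )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts: var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.maximum(mean, 1e-12) * dispersion)
    return rng.poisson(lam)


def simulate_counts(spec: SimSpec) -> tuple[CountMatrix, GroundTruth]:
    """Simulate the gene × cell count matrix and its ground truth.

    Per cell: library size lognormal; mitochondrial fraction Beta, imposed
    by rescaling the mitochondrial gene means to the drawn fraction; per
    gene negative-binomial counts around cluster-specific means (markers of
    the cell's cluster inflated by ``marker_fold_change``).  Low-quality
    cells (spread round-robin over clusters) get a library size far below
    the QC threshold and an elevated mitochondrial fraction.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_names()
    n_mito = len(MITO_GENES)
    mito_idx = np.arange(n_mito)
    gene_pos = {g: i for i, g in enumerate(genes)}
    markers = spec.marker_names()

    cells, cell_labels = [], []
    for label in spec.cluster_labels:
        for i in range(spec.n_cells_per_cluster):
            cells.append(f"{label}_c{i + 1:03d}")
            cell_labels.append(label)
    n_cells = len(cells)

    # low-quality cells: round-robin over clusters, last cells of each block
    lowq = []
    per_cluster_taken = {lab: 0 for lab in spec.cluster_labels}
    for i in range(spec.n_lowq_cells):
        lab = spec.cluster_labels[i % len(spec.cluster_labels)]
        per_cluster_taken[lab] += 1
        block = [j for j, l in enumerate(cell_labels) if l == lab]
        lowq.append(block[-per_cluster_taken[lab]])
    lowq = sorted(lowq)
    lowq_mask = np.zeros(n_cells, dtype=bool)
    lowq_mask[lowq] = True

    # base gene weights (relative expression) and mitochondrial weights
    weights = rng.lognormal(0.0, 1.0, size=len(genes))
    weights[mito_idx] = rng.lognormal(0.0, 0.5, size=n_mito)

    # per-cluster mean weights: markers (and the transgene) inflated
    cluster_weights = {}
    for label in spec.cluster_labels:
        w = weights.copy()
        for g in markers[label]:
            w[gene_pos[g]] *= spec.marker_fold_change
        if label == spec.transgene_cluster:
            w[gene_pos[spec.transgene]] *= spec.marker_fold_change
        cluster_weights[label] = w

    mu_log, sigma_log = spec.library_size_lognormal
    lib = rng.lognormal(mu_log, sigma_log, size=n_cells)
    lib[lowq_mask] = spec.lowq_library_size
    a, b = spec.mito_frac_beta
    frac = rng.beta(a, b, size=n_cells)
    la, lb = spec.lowq_mito_beta
    frac[lowq_mask] = rng.beta(la, lb, size=int(lowq_mask.sum()))

    mito_mask = np.zeros(len(genes), dtype=bool)
    mito_mask[mito_idx] = True
    mean = np.empty((len(genes), n_cells))
    for c in range(n_cells):
        w = cluster_weights[cell_labels[c]]
        p = np.empty_like(w)
        p[~mito_mask] = (1.0 - frac[c]) * w[~mito_mask] / w[~mito_mask].sum()
        p[mito_mask] = frac[c] * w[mito_mask] / w[mito_mask].sum()
        mean[:, c] = p * lib[c]

    counts = _nb_counts(rng, mean, spec.nb_dispersion)
    cm = CountMatrix(genes, cells, sp.csr_matrix(counts))

    gene_clusters: dict[str, set[str]] = {}
    for label in spec.cluster_labels:
        for g in markers[label]:
            gene_clusters.setdefault(g, set()).add(label)
    flags: dict[str, set[str]] = {g: set() for g in AT1_MARKER_GENES}
    for g in spec.conserved_markers:
        flags[g].add("conserved")
    for g in spec.lung_enriched_markers:
        flags[g].add("lung_enriched")
    for g in spec.membrane_markers:
        flags[g].add("membrane")

    truth = GroundTruth(
        cell_clusters=dict(zip(cells, cell_labels)),
        gene_clusters=gene_clusters,
        gene_flags=flags,
        lowq_cells=[cells[i] for i in lowq],
        genes=genes,
        transgene=spec.transgene,
    )
    return cm, truth


def simulate_organ_matrix(spec: SimSpec, seed: int | None = None) -> OrganExpressionMatrix:
    """Multi-organ bulk matrix in the second species' (human) namespace.

    Genes are the upper-cased simulated genes (mitochondrial genes and the
    transgene excluded).  Lung-enriched flagged genes have their lung organ
    mean inflated ``lung_fold``-fold; every other gene shares one mean
    across organs, with tight gamma noise so non-enriched genes fail a
    fold-2 specificity filter.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    mouse_genes = [g for g in spec.gene_names()
                   if g not in MITO_GENES and g != spec.transgene]
    genes = [g.upper() for g in mouse_genes]
    enriched = {canonical_symbol(g) for g in spec.lung_enriched_markers}

    organs = ["lung"] + [f"organ{i:02d}" for i in range(1, spec.n_organs)]
    samples, organ_of = [], {}
    for organ in organs:
        n = spec.n_lung_samples if organ == "lung" else spec.n_samples_per_organ
        for i in range(n):
            sid = f"{organ}_s{i + 1}"
            samples.append(sid)
            organ_of[sid] = organ

    base = rng.lognormal(np.log(50.0), 1.0, size=len(genes))
    values = np.empty((len(genes), len(samples)))
    organ_idx = {o: [j for j, s in enumerate(samples) if organ_of[s] == o]
                 for o in organs}
    for gi, gene in enumerate(genes):
        for organ in organs:
            m = base[gi]
            if organ == "lung" and canonical_symbol(gene) in enriched:
                m *= spec.lung_fold
            cols = organ_idx[organ]
            values[gi, cols] = rng.gamma(20.0, m / 20.0, size=len(cols))
    # per-sample depth differences, removed downstream by CPM normalization
    values *= rng.uniform(0.5, 2.0, size=len(samples))[None, :]
    return OrganExpressionMatrix(genes, samples, organ_of, values)


def simulate_external_sets(
    truth: GroundTruth,
    spec: SimSpec,
    dropout_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[list[GeneSet], OrthologMap, LocalizationTable, GeneSet]:
    """External resources: marker sets, ortholog map, localization, foreign set.

    Each of the three external mouse sets contains the true AT1 markers,
    each independently dropped with probability ``dropout_rate``, plus
    ``n_decoys_per_set`` random non-marker genes.  The ortholog map pairs
    every AT1 marker (always) and a ``ortholog_coverage`` fraction of the
    remaining genes with their upper-cased counterpart.  The foreign
    (human) differentiation gene set contains the conserved-flagged markers
    plus decoys.  The localization table annotates membrane-flagged markers
    as plasma-membrane, Rtkn2 as nuclear, and background genes at random.
    """
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must be in [0, 1)")
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    at1 = list(AT1_MARKER_GENES)
    marker_keys = {canonical_symbol(g) for g in truth.gene_clusters}
    pool = [g for g in truth.genes
            if canonical_symbol(g) not in marker_keys
            and g not in MITO_GENES and g != truth.transgene]

    external = []
    for name in ("mouse_atlas", "neonatal_lung", "at1_sorted"):
        kept = [g for g in at1 if rng.random() >= dropout_rate]
        decoys = list(rng.choice(pool, size=min(spec.n_decoys_per_set, len(pool)),
                                 replace=False))
        external.append(GeneSet(name, "mouse", kept + decoys))

    orthologs = OrthologMap()
    for g in truth.genes:
        if g in MITO_GENES or g == truth.transgene:
            continue
        always = canonical_symbol(g) in {canonical_symbol(m) for m in at1}
        if always or rng.random() < spec.ortholog_coverage:
            orthologs.add(g, g.upper())

    conserved = [g for g in at1 if "conserved" in truth.gene_flags.get(g, set())]
    foreign_decoys = [g.upper() for g in rng.choice(pool, size=min(spec.n_decoys_per_set, len(pool)), replace=False)]
    foreign = GeneSet("at2_at1_diff_model", "human",
                      [g.upper() for g in conserved] + foreign_decoys)

    entries: dict[str, str] = {}
    classes = np.array(["cytoplasm", "nuclear", "other", "plasma-membrane"])
    for g in pool:
        if rng.random() < 0.7:
            entries[g.upper()] = str(rng.choice(classes))
    for g in at1:
        flags = truth.gene_flags.get(g, set())
        if "membrane" in flags:
            entries[g.upper()] = "plasma-membrane"
        elif canonical_symbol(g) == "rtkn2":
            entries[g.upper()] = "nuclear"
        else:
            entries[g.upper()] = "cytoplasm"
    localization = LocalizationTable(entries)
    return external, orthologs, localization, foreign


def write_fixture(spec: SimSpec, directory) -> dict[str, Path]:
    """Emit the full fixture directory (counts, organ matrix, external
    resources, ground truth) and return the paths."""
    from .io_formats import write_count_matrix, write_gene_set

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cm, truth = simulate_counts(spec)
    organ = simulate_organ_matrix(spec)
    external, orthologs, localization, foreign = simulate_external_sets(truth, spec)

    paths = write_count_matrix(cm, directory)
    paths["organ_matrix"] = directory / "organ_matrix.csv"
    paths["organ_samples"] = directory / "organ_samples.tsv"
    organ.write(paths["organ_matrix"], paths["organ_samples"])
    for gs in external:
        p = directory / f"external_{gs.name}.tsv"
        write_gene_set(gs, p)
        paths[f"external_{gs.name}"] = p
    paths["foreign"] = directory / "foreign_diff_model.tsv"
    write_gene_set(foreign, paths["foreign"])
    paths["orthologs"] = directory / "orthologs.tsv"
    orthologs.to_tsv(paths["orthologs"])
    paths["localization"] = directory / "localization.tsv"
    localization.to_tsv(paths["localization"])
    paths["truth"] = directory / "ground_truth.json"
    truth.to_json(paths["truth"])
    return paths
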