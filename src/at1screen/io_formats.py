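"""Readers and writers for everything the pipeline touches on disk.

Supported formats
-----------------
* count matrices: MatrixMarket triplet (``matrix.mtx`` + ``genes.tsv`` +
  ``barcodes.tsv``, genes as rows) or a dense CSV (genes as rows, first
  column = gene symbol, header row = cell identifiers);
* gene lists: TSV, one symbol per row (first tab-separated field);
* ortholog maps: two-column TSV, one pair per row, symmetric lookup;
* multi-organ bulk matrices: CSV matrix plus a two-column sample→organ TSV;
* subcellular localization tables: two-column TSV (gene, class);
* run configuration: YAML;
* funnel reports: JSON, lossless round trip.

Gene symbols are canonicalized case-insensitively (``casefold``) for all
membership and identity checks, while the first-seen spelling is preserved
for display.  Mouse/human symbol conventions (``Ager`` vs ``AGER``) differ
only by case for the genes this screen cares about, so case-insensitive
identity is the one documented convention.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "canonical_symbol",
    "GeneSet",
    "CountMatrix",
    "OrthologMap",
    "OrganExpressionMatrix",
    "LocalizationTable",
    "RunConfig",
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_set",
    "write_gene_set",
    "write_funnel_report",
    "read_funnel_report",
]


class FormatError(ValueError):
    """Malformed or invariant-violating input file."""


def canonical_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: stripped and case-folded.

    Idempotent; used for every identity/membership comparison in the
    package.  Display casing is preserved separately by the containers.
    """
    return symbol.strip().casefold()


# ---------------------------------------------------------------------------
# GeneSet
# ---------------------------------------------------------------------------

class GeneSet:
    """A named, species-tagged set of gene symbols.

    Membership is case-insensitive; the first-seen spelling of each symbol
    is kept for display.  Duplicates (after canonicalization) are dropped
    and counted.
    """

    def __init__(self, name: str, species: str, symbols: Iterable[str] = ()):
        if not name:
            raise ValueError("GeneSet requires a non-empty name")
        self.name = name
        self.species = species
        self._display: dict[str, str] = {}
        self.n_duplicates = 0
        for s in symbols:
            key = canonical_symbol(s)
            if not key:
                continue
            if key in self._display:
                self.n_duplicates += 1
            else:
                self._display[key] = s.strip()

    # -- set protocol -------------------------------------------------------
    def __contains__(self, symbol: str) -> bool:
        return canonical_symbol(symbol) in self._display

    def __len__(self) -> int:
        return len(self._display)

    def __iter__(self):
        return iter(self.symbols())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GeneSet)
            and self.name == other.name
            and self.species == other.species
            and self.canonical() == other.canonical()
        )

    def __repr__(self) -> str:
        return f"GeneSet({self.name!r}, species={self.species!r}, n={len(self)})"

    def canonical(self) -> frozenset[str]:
        return frozenset(self._display)

    def symbols(self) -> list[str]:
        """Display spellings, sorted case-insensitively."""
        return sorted(self._display.values(), key=canonical_symbol)

    def display(self, symbol: str) -> str:
        return self._display[canonical_symbol(symbol)]

    def subset(self, keep: Iterable[str], name: str | None = None) -> "GeneSet":
        keys = {canonical_symbol(s) for s in keep}
        return GeneSet(
            name or self.name,
            self.species,
            [d for k, d in self._display.items() if k in keys],
        )


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Gene × cell matrix of non-negative integer read counts.

    ``counts`` is stored CSR-sparse with genes as rows.  Validation enforces
    dimension consistency, uniqueness of identifiers (genes compared
    case-insensitively) and integral non-negative entries.
    """

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.genes) or n_cells != len(self.cells):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        canon = [canonical_symbol(g) for g in self.genes]
        if len(set(canon)) != len(canon):
            dupes = sorted({c for c in canon if canon.count(c) > 1})
            raise FormatError(f"duplicate gene symbols after canonicalization: {dupes[:5]}")
        if len(set(self.cells)) != len(self.cells):
            raise FormatError("duplicate cell identifiers")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise FormatError("counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64)
        self._gene_index = {c: i for i, c in enumerate(canon)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_row(self, symbol: str) -> int:
        """Row index of a gene, case-insensitive; KeyError if absent."""
        return self._gene_index[canonical_symbol(symbol)]

    def has_gene(self, symbol: str) -> bool:
        return canonical_symbol(symbol) in self._gene_index

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def subset_cells(self, cell_ids: Sequence[str]) -> "CountMatrix":
        pos = {c: i for i, c in enumerate(self.cells)}
        idx = [pos[c] for c in cell_ids]
        return CountMatrix(list(self.genes), list(cell_ids), self.counts[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.genes, columns=self.cells)


def read_count_matrix(
    path,
    genes_path=None,
    cells_path=None,
) -> CountMatrix:
    """Read a count matrix from MatrixMarket triplet files or a dense CSV.

    ``path`` ending in ``.mtx`` expects ``genes_path``/``cells_path``
    (defaulting to sibling ``genes.tsv``/``barcodes.tsv``); MatrixMarket
    1-based coordinates are converted by the reader.  ``path`` ending in
    ``.csv`` expects genes as rows, first column symbols, header cell ids.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.suffix == ".mtx":
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        cells_path = Path(cells_path) if cells_path else path.parent / "barcodes.tsv"
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FormatError(f"{p}: no such file")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # header / coordinate problems
            raise FormatError(f"{path}: malformed MatrixMarket file ({exc})") from exc
        genes = [
            line.split("\t")[0].strip()
            for line in genes_path.read_text().splitlines()
            if line.strip()
        ]
        cells = [
            line.split("\t")[0].strip()
            for line in cells_path.read_text().splitlines()
            if line.strip()
        ]
        try:
            return CountMatrix(genes, cells, sp.csr_matrix(mat))
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if path.suffix in {".csv", ".tsv"}:
        sep = "," if path.suffix == ".csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise FormatError(f"{path}: unreadable table ({exc})") from exc
        values = df.to_numpy()
        if values.size == 0:
            raise FormatError(f"{path}: empty count table")
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError(f"{path}: non-numeric entries in count table")
        try:
            return CountMatrix(
                [str(g) for g in df.index],
                [str(c) for c in df.columns],
                sp.csr_matrix(values),
            )
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    raise FormatError(f"{path}: unsupported count-matrix extension {path.suffix!r}")


def write_count_matrix(cm: CountMatrix, directory) -> dict[str, Path]:
    """Write the MatrixMarket triplet into ``directory``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "matrix.mtx",
        "genes": directory / "genes.tsv",
        "cells": directory / "barcodes.tsv",
    }
    scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(cm.counts), field="integer")
    paths["genes"].write_text("".join(f"{g}\n" for g in cm.genes))
    paths["cells"].write_text("".join(f"{c}\n" for c in cm.cells))
    return paths


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------

_HEADER_TOKENS = {"gene", "genes", "symbol", "gene_symbol", "gene_id"}


def read_gene_set(path, name: str | None = None, species: str = "") -> GeneSet:
    """Read a gene set from a TSV with one symbol per row (first field).

    A leading header row whose first field is a common column name
    (``gene``, ``symbol``, ...) is skipped.  An empty result is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if lines and canonical_symbol(lines[0].split("\t")[0]) in _HEADER_TOKENS:
        lines = lines[1:]
    symbols = [ln.split("\t")[0].strip() for ln in lines]
    gs = GeneSet(name or path.stem, species, symbols)
    if len(gs) == 0:
        raise FormatError(f"{path}: gene set is empty")
    if gs.n_duplicates:
        logger.info("%s: dropped %d duplicate symbols", path, gs.n_duplicates)
    return gs


def write_gene_set(gs: GeneSet, path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in gs.symbols()))


# ---------------------------------------------------------------------------
# OrthologMap
# ---------------------------------------------------------------------------

class OrthologMap:
    """Many-to-many mapping between the gene symbols of two species.

    Lookup is symmetric: ``orthologs_of`` returns the counterparts recorded
    in either column.  Unmapped symbols yield an empty set, never an error.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._map: dict[str, set[str]] = {}
        self.n_pairs = 0
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        ka, kb = canonical_symbol(a), canonical_symbol(b)
        if not ka or not kb:
            return
        self._map.setdefault(ka, set()).add(b.strip())
        self._map.setdefault(kb, set()).add(a.strip())
        self.n_pairs += 1

    def orthologs_of(self, symbol: str) -> set[str]:
        partners = set(self._map.get(canonical_symbol(symbol), set()))
        # for case-only pairs (Ager<->AGER) drop the query's own spelling
        trimmed = partners - {symbol.strip()}
        return trimmed if trimmed else partners

    def __contains__(self, symbol: str) -> bool:
        return canonical_symbol(symbol) in self._map

    @classmethod
    def from_tsv(cls, path) -> "OrthologMap":
        path = Path(path)
        if not path.exists():
            raise FormatError(f"{path}: no such file")
        pairs = []
        for i, ln in enumerate(path.read_text().splitlines(), 1):
            if not ln.strip():
                continue
            fields = ln.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{i}: expected two tab-separated symbols")
            if i == 1 and canonical_symbol(fields[0]) in _HEADER_TOKENS:
                continue
            pairs.append((fields[0], fields[1]))
        return cls(pairs)

    def to_tsv(self, path) -> None:
        seen = set()
        lines = []
        for key, partners in sorted(self._map.items()):
            for p in sorted(partners):
                edge = frozenset((key, canonical_symbol(p)))
                if edge in seen:
                    continue
                seen.add(edge)
                lines.append(f"{key}\t{p}\n")
        Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# OrganExpressionMatrix
# ---------------------------------------------------------------------------

@dataclass
class OrganExpressionMatrix:
    """Gene × sample bulk expression with one organ label per sample."""

    genes: list[str]
    samples: list[str]
    organ_of: dict[str, str]
    values: np.ndarray  # gene x sample, counts or CPM

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise FormatError(
                f"organ matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        missing = [s for s in self.samples if s not in self.organ_of]
        if missing:
            raise FormatError(f"samples without organ label: {missing[:5]}")
        if np.any(self.values < 0):
            raise FormatError("negative expression values in organ matrix")
        if len(self.organs) < 2:
            raise FormatError("organ matrix needs at least two distinct organs")
        self._gene_index = {canonical_symbol(g): i for i, g in enumerate(self.genes)}

    @property
    def organs(self) -> list[str]:
        return sorted({self.organ_of[s] for s in self.samples})

    def has_gene(self, symbol: str) -> bool:
        return canonical_symbol(symbol) in self._gene_index

    def gene_row(self, symbol: str) -> int:
        return self._gene_index[canonical_symbol(symbol)]

    def cpm(self) -> np.ndarray:
        """Per-sample counts-per-million normalization of ``values``."""
        totals = self.values.sum(axis=0)
        safe = np.where(totals > 0, totals, 1.0)
        return self.values / safe * 1e6

    def sample_columns(self, organ: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if self.organ_of[s] == organ])

    @classmethod
    def read(cls, matrix_path, organs_path) -> "OrganExpressionMatrix":
        matrix_path, organs_path = Path(matrix_path), Path(organs_path)
        for p in (matrix_path, organs_path):
            if not p.exists():
                raise FormatError(f"{p}: no such file")
        df = pd.read_csv(matrix_path, index_col=0)
        organ_of = {}
        for i, ln in enumerate(organs_path.read_text().splitlines(), 1):
            if not ln.strip():
                continue
            fields = ln.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{organs_path}:{i}: expected sample<TAB>organ")
            if i == 1 and canonical_symbol(fields[0]) in {"sample", "sample_id"}:
                continue
            organ_of[fields[0].strip()] = fields[1].strip()
        return cls(
            [str(g) for g in df.index],
            [str(s) for s in df.columns],
            organ_of,
            df.to_numpy(dtype=float),
        )

    def write(self, matrix_path, organs_path) -> None:
        pd.DataFrame(self.values, index=self.genes, columns=self.samples).to_csv(matrix_path)
        Path(organs_path).write_text(
            "".join(f"{s}\t{self.organ_of[s]}\n" for s in self.samples)
        )


# ---------------------------------------------------------------------------
# LocalizationTable
# ---------------------------------------------------------------------------

class LocalizationTable:
    """Gene → subcellular localization class; unknown genes map to "unknown"."""

    UNKNOWN = "unknown"

    def __init__(self, entries: Mapping[str, str] | Iterable[tuple[str, str]] = ()):
        items = entries.items() if isinstance(entries, Mapping) else entries
        self._entries = {canonical_symbol(g): c.strip() for g, c in items}

    def get(self, symbol: str) -> str:
        return self._entries.get(canonical_symbol(symbol), self.UNKNOWN)

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_tsv(cls, path) -> "LocalizationTable":
        path = Path(path)
        if not path.exists():
            raise FormatError(f"{path}: no such file")
        entries = []
        for i, ln in enumerate(path.read_text().splitlines(), 1):
            if not ln.strip():
                continue
            fields = ln.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{i}: expected gene<TAB>class")
            if i == 1 and canonical_symbol(fields[0]) in _HEADER_TOKENS:
                continue
            entries.append((fields[0], fields[1]))
        return cls(entries)

    def to_tsv(self, path) -> None:
        Path(path).write_text(
            "".join(f"{g}\t{c}\n" for g, c in sorted(self._entries.items()))
        )


# ---------------------------------------------------------------------------
# RunConfig
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with the published defaults.

    QC thresholds are the three printed cell filters (total counts > 90,000,
    detected genes > 500, mitochondrial fraction < 0.15, all strict).
    Clustering parameters (HVG count, PCs, neighbors, resolution) and the
    marker/funnel settings are surfaced here rather than hidden in code.
    """

    # cell QC
    min_counts: float = 90_000.0
    min_genes: int = 500
    max_mito_frac: float = 0.15
    mito_prefix: str = "mt-"
    count_transgene_in_qc: bool = True
    # transgenes/reporters: counted in QC, never marker candidates
    exclude_genes: tuple[str, ...] = ("tdTomato",)
    # normalization
    scale: float = 1e6
    # clustering
    n_hvg: int = 1000
    n_pcs: int = 10
    k_neighbors: int = 15
    resolution: float = 1.0
    # markers
    top_n: int = 100
    adjust_method: str = "fdr_bh"
    # funnel
    intersect_mode: str = "all"
    target_organ: str = "lung"
    specificity_fold: float = 2.0
    specificity_floor: float = 1.0
    specificity_aggregate: str = "median"
    allowed_localizations: tuple[str, ...] = ("plasma-membrane",)
    unknown_localization_policy: str = "drop"  # or "keep"
    # provenance
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("min_counts", "max_mito_frac", "resolution", "scale",
                     "specificity_fold", "specificity_floor"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"RunConfig.{name} must be finite, got {v}")
        for name in ("min_genes", "n_hvg", "n_pcs", "k_neighbors", "top_n", "seed"):
            int(getattr(self, name))
        if self.specificity_aggregate not in {"median", "mean"}:
            raise ValueError("specificity_aggregate must be 'median' or 'mean'")
        if self.unknown_localization_policy not in {"drop", "keep"}:
            raise ValueError("unknown_localization_policy must be 'drop' or 'keep'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exclude_genes"] = list(self.exclude_genes)
        d["allowed_localizations"] = list(self.allowed_localizations)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        for key in ("exclude_genes", "allowed_localizations"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Funnel report (JSON)
# ---------------------------------------------------------------------------

def write_funnel_report(result, path) -> None:
    """Serialize a marker_screen.FunnelResult to JSON (lossless)."""
    payload = {
        "stages": [
            {
                "name": st.name,
                "input_size": len(st.input_set),
                "output_size": len(st.output_set),
                "input": {"name": st.input_set.name, "species": st.input_set.species,
                          "genes": st.input_set.symbols()},
                "output": {"name": st.output_set.name, "species": st.output_set.species,
                           "genes": st.output_set.symbols()},
                "parameters": st.parameters,
                "audit": st.audit,
            }
            for st in result.stages
        ],
        "final_ranking": result.final_ranking,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_funnel_report(path):
    """Read a funnel report written by :func:`write_funnel_report`."""
    from .marker_screen import FunnelResult, FunnelStage  # local: avoid cycle

    with open(path) as fh:
        payload = json.load(fh)
    stages = []
    for st in payload["stages"]:
        stages.append(
            FunnelStage(
                name=st["name"],
                input_set=GeneSet(st["input"]["name"], st["input"]["species"],
                                  st["input"]["genes"]),
                output_set=GeneSet(st["output"]["name"], st["output"]["species"],
                                   st["output"]["genes"]),
                parameters=st["parameters"],
                audit=st["audit"],
            )
        )
    return FunnelResult(stages=stages,
                        final_ranking=[list(r) for r in payload["final_ranking"]])
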