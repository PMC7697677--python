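"""Per-cell quality metrics and the three-filter cell selection.

Cells are kept when all of the following hold, as strict inequalities:
total counts > ``min_counts`` (default 90,000), detected genes >
``min_genes`` (default 500), and mitochondrial read fraction <
``max_mito_frac`` (default 0.15).  A cell sitting exactly on a threshold
is removed; the boundary convention is tested, not incidental.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, RunConfig, canonical_symbol

logger = logging.getLogger(__name__)

__all__ = ["CellQCProfile", "QCReport", "compute_qc_profiles", "filter_cells"]


@dataclass
class CellQCProfile:
    """QC metrics for one cell.

    ``mito_fraction`` is mitochondrial counts over total counts; a cell
    with zero total counts gets 0.0 by convention.
    """

    cell: str
    total_counts: int
    n_genes_detected: int
    mito_fraction: float

    def __post_init__(self):
        if not 0.0 <= self.mito_fraction <= 1.0:
            raise ValueError(f"mito_fraction out of [0,1]: {self.mito_fraction}")
        if self.total_counts < 0 or self.n_genes_detected < 0:
            raise ValueError("negative QC metric")


def compute_qc_profiles(
    cm: CountMatrix,
    mito_prefix: str = "mt-",
    exclude_genes: tuple[str, ...] = (),
) -> list[CellQCProfile]:
    """One profile per cell.

    Mitochondrial genes are identified by a case-insensitive symbol prefix
    (mouse ``mt-``, human ``MT-``).  ``exclude_genes`` removes rows (e.g. a
    reporter transgene) from the totals when the run is configured not to
    count them; by default the transgene counts like any other gene.
    """
    prefix = canonical_symbol(mito_prefix)
    excluded = {canonical_symbol(g) for g in exclude_genes}
    keep = np.array(
        [canonical_symbol(g) not in excluded for g in cm.genes], dtype=bool
    )
    mito = np.array(
        [canonical_symbol(g).startswith(prefix) for g in cm.genes], dtype=bool
    ) & keep

    counts = cm.counts
    totals = np.asarray(counts[keep].sum(axis=0)).ravel()
    detected = np.asarray((counts[keep] > 0).sum(axis=0)).ravel()
    mito_totals = (
        np.asarray(counts[mito].sum(axis=0)).ravel()
        if mito.any()
        else np.zeros(cm.n_cells)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito_totals / np.maximum(totals, 1), 0.0)
    return [
        CellQCProfile(cell, int(t), int(d), float(f))
        for cell, t, d, f in zip(cm.cells, totals, detected, frac)
    ]


@dataclass
class QCReport:
    """Per-filter failure counts and the full per-cell pass/fail table."""

    n_input: int
    n_kept: int
    n_fail_counts: int
    n_fail_genes: int
    n_fail_mito: int
    table: pd.DataFrame  # cell, total_counts, n_genes_detected, mito_fraction, pass_* , kept

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def filter_cells(
    profiles: list[CellQCProfile], config: RunConfig
) -> tuple[list[str], QCReport]:
    """Apply the three strict QC filters; returns kept cell ids and a report.

    A cell can fail several filters; each failure is counted per filter.
    An empty kept set is allowed (warned, not an error).
    """
    rows = []
    for p in profiles:
        pass_counts = p.total_counts > config.min_counts
        pass_genes = p.n_genes_detected > config.min_genes
        pass_mito = p.mito_fraction < config.max_mito_frac
        rows.append(
            {
                "cell": p.cell,
                "total_counts": p.total_counts,
                "n_genes_detected": p.n_genes_detected,
                "mito_fraction": p.mito_fraction,
                "pass_counts": pass_counts,
                "pass_genes": pass_genes,
                "pass_mito": pass_mito,
                "kept": pass_counts and pass_genes and pass_mito,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cell", "total_counts", "n_genes_detected", "mito_fraction",
            "pass_counts", "pass_genes", "pass_mito", "kept",
        ],
    )
    kept = list(table.loc[table["kept"], "cell"]) if len(table) else []
    report = QCReport(
        n_input=len(profiles),
        n_kept=len(kept),
        n_fail_counts=int((~table["pass_counts"]).sum()) if len(table) else 0,
        n_fail_genes=int((~table["pass_genes"]).sum()) if len(table) else 0,
        n_fail_mito=int((~table["pass_mito"]).sum()) if len(table) else 0,
        table=table,
    )
    if not kept:
        logger.warning("QC filtering removed every cell")
    return kept, report
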