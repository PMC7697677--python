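"""The candidate-marker funnel.

Ordered, set-shrinking screen over the top cluster-enriched genes:

1. cross-dataset intersection with externally published marker sets;
2. cross-species conservation through an ortholog map against a
   differentiation-model gene list from the second species;
3. tissue specificity on a multi-organ bulk expression matrix
   (per-organ aggregate CPM, target organ >= fold x the best other organ
   and above an absolute floor);
4. subcellular localization (keep plasma-membrane annotated genes).

Every stage records a per-gene audit (which sets/filters were passed or
failed), stage outputs are always subsets of their inputs, and the final
candidates are ranked by tissue-specificity fold, then adjusted p, then
symbol.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    GeneSet,
    LocalizationTable,
    OrganExpressionMatrix,
    OrthologMap,
    RunConfig,
    canonical_symbol,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FunnelStage",
    "FunnelResult",
    "SpecificityScore",
    "intersect_with_external",
    "conserved_intersection",
    "tissue_specificity_filter",
    "localization_filter",
    "run_funnel",
]


@dataclass
class FunnelStage:
    name: str
    input_set: GeneSet
    output_set: GeneSet
    parameters: dict
    audit: dict[str, str]  # display symbol -> "kept" or failure reason

    def __post_init__(self):
        if not self.output_set.canonical() <= self.input_set.canonical():
            raise ValueError(f"stage {self.name}: output is not a subset of input")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FunnelStage)
            and self.name == other.name
            and self.input_set == other.input_set
            and self.output_set == other.output_set
            and self.parameters == other.parameters
            and self.audit == other.audit
        )


@dataclass
class FunnelResult:
    stages: list[FunnelStage]
    final_ranking: list[list] = field(default_factory=list)  # [gene, fold, adjusted_p]

    @property
    def final_set(self) -> GeneSet:
        return self.stages[-1].output_set

    def stage_sizes(self) -> list[tuple[str, int, int]]:
        return [(s.name, len(s.input_set), len(s.output_set)) for s in self.stages]

    def terminal_status(self) -> dict[str, str]:
        """Each stage-1 candidate's fate: 'survived' or 'failed@<stage>: <why>'."""
        status: dict[str, str] = {}
        for gene in self.stages[0].input_set.symbols():
            status[gene] = "survived"
            for st in self.stages:
                if gene not in st.input_set:
                    continue
                verdict = st.audit.get(st.input_set.display(gene), "kept")
                if verdict != "kept":
                    status[gene] = f"failed@{st.name}: {verdict}"
                    break
        return status

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FunnelResult)
            and self.stages == other.stages
            and self.final_ranking == other.final_ranking
        )


@dataclass
class SpecificityScore:
    """Per-gene organ-specificity summary on the CPM scale."""

    gene: str
    target_aggregate: float
    max_other_aggregate: float
    fold: float
    enriched: bool


def _stage(name, input_set, survivors, audit, parameters, out_name) -> FunnelStage:
    return FunnelStage(
        name=name,
        input_set=input_set,
        output_set=input_set.subset(survivors, name=out_name),
        parameters=parameters,
        audit=audit,
    )


def intersect_with_external(
    candidates: GeneSet,
    external: list[GeneSet],
    mode: str = "all",
) -> FunnelStage:
    """Keep candidates present in the external marker sets.

    ``mode="all"`` requires membership in every external set;
    ``mode="k-of-m"`` (e.g. ``"2-of-3"``) requires membership in at least
    k of the m sets.  An empty external list is the identity (warned).
    """
    params = {"mode": mode, "external_sets": [e.name for e in external]}
    if not external:
        warnings.warn("no external sets supplied; intersection stage is the identity")
        audit = {g: "kept" for g in candidates.symbols()}
        return _stage("cross_dataset", candidates, candidates.symbols(), audit,
                      params, "cross_dataset_conserved")
    if mode == "all":
        required = len(external)
    else:
        try:
            k, m = mode.split("-of-")
            required = int(k)
            if int(m) != len(external):
                raise ValueError
        except ValueError:
            raise ValueError(f"bad intersection mode {mode!r} for {len(external)} sets")
    audit, survivors = {}, []
    for gene in candidates.symbols():
        hits = [e.name for e in external if gene in e]
        if len(hits) >= required:
            audit[gene] = "kept"
            survivors.append(gene)
        else:
            missing = [e.name for e in external if gene not in e]
            audit[gene] = f"absent from {len(missing)} set(s): {', '.join(missing)}"
    return _stage("cross_dataset", candidates, survivors, audit, params,
                  "cross_dataset_conserved")


def conserved_intersection(
    candidates: GeneSet,
    foreign: GeneSet,
    orthologs: OrthologMap,
) -> FunnelStage:
    """Keep candidates with at least one ortholog in the foreign gene set.

    Any-match rule for one-to-many orthologs; candidates without a mapping
    are dropped and audited as ``no ortholog``.
    """
    params = {"foreign_set": foreign.name, "foreign_species": foreign.species}
    audit, survivors = {}, []
    for gene in candidates.symbols():
        partners = orthologs.orthologs_of(gene)
        if not partners:
            audit[gene] = "no ortholog"
        elif any(p in foreign for p in partners):
            audit[gene] = "kept"
            survivors.append(gene)
        else:
            audit[gene] = "ortholog not in foreign set"
    return _stage("cross_species", candidates, survivors, audit, params,
                  "cross_species_conserved")


def _map_to_matrix(gene: str, matrix: OrganExpressionMatrix,
                   orthologs: OrthologMap | None) -> str | None:
    """Resolve a candidate to a row of the organ matrix.

    Direct case-insensitive symbol match first (mouse/human casing), then
    any ortholog of the gene.
    """
    if matrix.has_gene(gene):
        return gene
    if orthologs is not None:
        for p in sorted(orthologs.orthologs_of(gene), key=canonical_symbol):
            if matrix.has_gene(p):
                return p
    return None


def tissue_specificity_filter(
    candidates: GeneSet,
    matrix: OrganExpressionMatrix,
    target_organ: str = "lung",
    fold: float = 2.0,
    floor: float = 1.0,
    aggregate: str = "median",
    orthologs: OrthologMap | None = None,
) -> tuple[FunnelStage, dict[str, SpecificityScore]]:
    """Keep candidates enriched in the target organ of a bulk matrix.

    Samples are CPM-normalized, aggregated per organ (median by default);
    a gene is enriched iff target aggregate >= ``fold`` x the maximum
    other-organ aggregate and >= ``floor``.  Candidates absent from the
    matrix (directly or via orthologs) are dropped as "not measured".
    """
    if target_organ not in matrix.organs:
        raise ValueError(f"target organ {target_organ!r} not in matrix organs")
    agg = np.median if aggregate == "median" else np.mean
    cpm = matrix.cpm()
    organ_cols = {o: matrix.sample_columns(o) for o in matrix.organs}
    params = {"target_organ": target_organ, "fold": fold, "floor": floor,
              "aggregate": aggregate}
    audit, survivors, scores = {}, [], {}
    for gene in candidates.symbols():
        mapped = _map_to_matrix(gene, matrix, orthologs)
        if mapped is None:
            audit[gene] = "not measured"
            continue
        row = cpm[matrix.gene_row(mapped)]
        target = float(agg(row[organ_cols[target_organ]]))
        others = [float(agg(row[organ_cols[o]])) for o in matrix.organs
                  if o != target_organ]
        max_other = max(others)
        gene_fold = target / max_other if max_other > 0 else float("inf") if target > 0 else 0.0
        enriched = target >= fold * max_other and target >= floor
        scores[gene] = SpecificityScore(gene, target, max_other, gene_fold, enriched)
        if enriched:
            audit[gene] = "kept"
            survivors.append(gene)
        else:
            audit[gene] = (
                f"not {target_organ}-enriched "
                f"(target={target:.3g}, max_other={max_other:.3g})"
            )
    stage = _stage("tissue_specificity", candidates, survivors, audit, params,
                   f"{target_organ}_enriched")
    return stage, scores


def localization_filter(
    candidates: GeneSet,
    table: LocalizationTable,
    allowed_classes: tuple[str, ...] = ("plasma-membrane",),
    unknown_policy: str = "drop",
    orthologs: OrthologMap | None = None,
) -> FunnelStage:
    """Keep candidates whose protein localization class is allowed.

    Lookup is case-insensitive on the symbol and falls back to orthologs
    (localization annotation is typically in the second species'
    namespace).  ``unknown_policy="drop"`` removes unannotated genes
    (audited); ``"keep"`` retains them.
    """
    allowed = {c.strip() for c in allowed_classes}
    params = {"allowed_classes": sorted(allowed), "unknown_policy": unknown_policy}
    audit, survivors = {}, []
    for gene in candidates.symbols():
        cls = table.get(gene)
        if cls == LocalizationTable.UNKNOWN and orthologs is not None:
            for p in sorted(orthologs.orthologs_of(gene), key=canonical_symbol):
                cls = table.get(p)
                if cls != LocalizationTable.UNKNOWN:
                    break
        if cls in allowed:
            audit[gene] = "kept"
            survivors.append(gene)
        elif cls == LocalizationTable.UNKNOWN and unknown_policy == "keep":
            audit[gene] = "kept"
            survivors.append(gene)
        else:
            audit[gene] = f"localization: {cls}"
    return _stage("localization", candidates, survivors, audit, params,
                  "membrane_candidates")


def run_funnel(
    marker_table: pd.DataFrame,
    external_sets: list[GeneSet],
    foreign_set: GeneSet,
    orthologs: OrthologMap,
    organ_matrix: OrganExpressionMatrix,
    localization: LocalizationTable,
    config: RunConfig,
) -> FunnelResult:
    """Execute the full screen from a cluster's marker table.

    Stages run in fixed order (top-N candidates → cross-dataset →
    cross-species → tissue specificity → localization); each output is a
    subset of its input, checked at construction.  The final candidates are
    ranked by specificity fold (descending), adjusted p (ascending), then
    symbol.  Any stage failure aborts with the stage name in the message.
    """
    from .cluster_markers import top_n_markers  # local: avoid import cycle

    candidates = top_n_markers(
        marker_table, config.top_n,
        name=f"top_{config.top_n}_markers",
    )
    stage0 = FunnelStage(
        name="cluster_enriched",
        input_set=candidates,
        output_set=candidates,
        parameters={"top_n": config.top_n},
        audit={g: "kept" for g in candidates.symbols()},
    )
    stages = [stage0]
    try:
        st1 = intersect_with_external(candidates, external_sets, config.intersect_mode)
        stages.append(st1)
        st2 = conserved_intersection(st1.output_set, foreign_set, orthologs)
        stages.append(st2)
        st3, scores = tissue_specificity_filter(
            st2.output_set, organ_matrix,
            target_organ=config.target_organ,
            fold=config.specificity_fold,
            floor=config.specificity_floor,
            aggregate=config.specificity_aggregate,
            orthologs=orthologs,
        )
        stages.append(st3)
        st4 = localization_filter(
            st3.output_set, localization,
            allowed_classes=config.allowed_localizations,
            unknown_policy=config.unknown_localization_policy,
            orthologs=orthologs,
        )
        stages.append(st4)
    except Exception as exc:
        raise RuntimeError(f"funnel aborted at stage {len(stages)}: {exc}") from exc

    padj = {canonical_symbol(g): float(p)
            for g, p in zip(marker_table["gene"], marker_table["adjusted_p"])}
    ranking = sorted(
        (
            [g, scores[g].fold if g in scores else float("nan"),
             padj.get(canonical_symbol(g), float("nan"))]
            for g in st4.output_set.symbols()
        ),
        key=lambda r: (-r[1], r[2], canonical_symbol(r[0])),
    )
    result = FunnelResult(stages=stages, final_ranking=ranking)
    sizes = " -> ".join(str(len(s.output_set)) for s in stages)
    logger.info("funnel sizes: %s", sizes)
    return result
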