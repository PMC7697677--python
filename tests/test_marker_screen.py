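"""Funnel stages: set algebra, conservation, specificity, localization."""

import numpy as np
import pytest

from at1screen.io_formats import (
    GeneSet,
    LocalizationTable,
    OrganExpressionMatrix,
    OrthologMap,
    RunConfig,
    read_funnel_report,
    write_funnel_report,
)
from at1screen.marker_screen import (
    conserved_intersection,
    intersect_with_external,
    localization_filter,
    run_funnel,
    tissue_specificity_filter,
)


def _set(name, *genes, species="mouse"):
    return GeneSet(name, species, genes)


class TestCrossDataset:
    def test_mode_all_is_set_intersection(self):
        st = intersect_with_external(
            _set("cand", "a", "b", "c"),
            [_set("e1", "a", "b"), _set("e2", "a", "c")],
            mode="all",
        )
        assert st.output_set.canonical() == {"a"}
        assert st.audit["b"].startswith("absent")

    def test_one_of_two_is_union_membership(self):
        st = intersect_with_external(
            _set("cand", "a", "b", "c"),
            [_set("e1", "a", "b"), _set("e2", "a", "c")],
            mode="1-of-2",
        )
        assert st.output_set.canonical() == {"a", "b", "c"}

    def test_disjoint_set_empties_output(self):
        st = intersect_with_external(
            _set("cand", "a", "b"), [_set("e1", "x", "y")], mode="all"
        )
        assert len(st.output_set) == 0

    def test_no_external_sets_is_identity_with_warning(self):
        with pytest.warns(UserWarning):
            st = intersect_with_external(_set("cand", "a"), [], mode="all")
        assert st.output_set.canonical() == {"a"}


class TestCrossSpecies:
    def test_ortholog_in_foreign_set_is_kept(self):
        st = conserved_intersection(
            _set("cand", "Ager"),
            _set("foreign", "AGER", species="human"),
            OrthologMap([("Ager", "AGER")]),
        )
        assert st.output_set.canonical() == {"ager"}

    def test_unmapped_gene_dropped_and_audited(self):
        st = conserved_intersection(
            _set("cand", "Mystery"),
            _set("foreign", "AGER", species="human"),
            OrthologMap([("Ager", "AGER")]),
        )
        assert len(st.output_set) == 0
        assert st.audit["Mystery"] == "no ortholog"

    def test_one_to_many_any_match_rule(self):
        st = conserved_intersection(
            _set("cand", "Dup1"),
            _set("foreign", "HUMB", species="human"),
            OrthologMap([("Dup1", "HUMA"), ("Dup1", "HUMB")]),
        )
        assert st.output_set.canonical() == {"dup1"}


def _organ_matrix(gene_values):
    """Three organs x two samples each; gene_values: gene -> per-organ mean."""
    organs = ["lung", "liver", "brain"]
    samples, organ_of = [], {}
    for o in organs:
        for i in (1, 2):
            s = f"{o}{i}"
            samples.append(s)
            organ_of[s] = o
    genes = list(gene_values)
    values = np.array(
        [[gene_values[g][organ_of[s]] for s in samples] for g in genes],
        dtype=float,
    )
    # pad with a constant housekeeping backbone so CPM scaling is stable
    genes.append("BACKBONE")
    values = np.vstack([values, np.full(len(samples), 1000.0)])
    return OrganExpressionMatrix(genes, samples, organ_of, values)


class TestTissueSpecificity:
    def test_constructed_enriched_gene_passes(self):
        m = _organ_matrix({"AGER": {"lung": 100, "liver": 5, "brain": 2}})
        st, scores = tissue_specificity_filter(
            _set("cand", "AGER", species="human"), m, fold=2.0, floor=1.0
        )
        assert st.output_set.canonical() == {"ager"}
        assert scores["AGER"].enriched and scores["AGER"].fold > 2

    def test_uniform_gene_fails_any_fold_above_one(self):
        m = _organ_matrix({"FLAT": {"lung": 50, "liver": 50, "brain": 50}})
        st, _ = tissue_specificity_filter(
            _set("cand", "FLAT", species="human"), m, fold=1.5
        )
        assert len(st.output_set) == 0

    def test_floor_blocks_silent_genes(self):
        m = _organ_matrix({"OFF": {"lung": 0, "liver": 0, "brain": 0}})
        st, _ = tissue_specificity_filter(
            _set("cand", "OFF", species="human"), m, fold=2.0, floor=1.0
        )
        assert len(st.output_set) == 0

    def test_unmeasured_gene_audited_as_not_measured(self):
        m = _organ_matrix({"AGER": {"lung": 100, "liver": 5, "brain": 2}})
        st, _ = tissue_specificity_filter(
            _set("cand", "Ghost", species="human"), m
        )
        assert st.audit["Ghost"] == "not measured"

    def test_mouse_candidate_resolved_case_insensitively(self):
        m = _organ_matrix({"AGER": {"lung": 100, "liver": 5, "brain": 2}})
        st, _ = tissue_specificity_filter(_set("cand", "Ager"), m)
        assert st.output_set.canonical() == {"ager"}

    def test_missing_target_organ_is_error(self):
        m = _organ_matrix({"AGER": {"lung": 1, "liver": 1, "brain": 1}})
        with pytest.raises(ValueError, match="target organ"):
            tissue_specificity_filter(_set("c", "AGER"), m, target_organ="kidney")


class TestLocalization:
    def test_membrane_kept_nuclear_dropped(self):
        table = LocalizationTable({"GPRC5A": "plasma-membrane", "RTKN2": "nuclear"})
        st = localization_filter(
            _set("cand", "GPRC5A", "RTKN2", species="human"), table
        )
        assert st.output_set.canonical() == {"gprc5a"}
        assert st.audit["RTKN2"] == "localization: nuclear"

    def test_allowing_every_class_is_identity(self):
        table = LocalizationTable({"A": "nuclear", "B": "cytoplasm"})
        st = localization_filter(
            _set("cand", "A", "B"), table,
            allowed_classes=("nuclear", "cytoplasm", "unknown"),
            unknown_policy="keep",
        )
        assert st.output_set.canonical() == {"a", "b"}

    def test_unknown_dropped_by_default_kept_on_keep_policy(self):
        table = LocalizationTable({})
        dropped = localization_filter(_set("c", "X"), table)
        kept = localization_filter(_set("c", "X"), table, unknown_policy="keep")
        assert len(dropped.output_set) == 0 and dropped.audit["X"].endswith("unknown")
        assert kept.output_set.canonical() == {"x"}


class TestRunFunnel:
    def test_end_to_end_recovers_planted_set_exactly(self, pipeline_result,
                                                     sim_bundle):
        planted = sim_bundle["truth"].conserved_membrane_markers
        assert pipeline_result.funnel.final_set.canonical() == {
            g.casefold() for g in planted
        }

    def test_stage_outputs_are_nested(self, pipeline_result):
        stages = pipeline_result.funnel.stages
        for prev, nxt in zip(stages, stages[1:]):
            assert nxt.input_set.canonical() == prev.output_set.canonical()
            assert nxt.output_set.canonical() <= nxt.input_set.canonical()

    def test_every_candidate_has_terminal_status(self, pipeline_result):
        funnel = pipeline_result.funnel
        status = funnel.terminal_status()
        assert set(status) == set(funnel.stages[0].input_set.symbols())
        survivors = {g for g, s in status.items() if s == "survived"}
        assert survivors == set(funnel.final_set.symbols())
        for s in status.values():
            assert s == "survived" or s.startswith("failed@")

    def test_funnel_deterministic_given_inputs(self, sim_bundle, pipeline_result):
        again = run_funnel(
            pipeline_result.marker_tables[pipeline_result.target_cluster],
            sim_bundle["external"],
            sim_bundle["foreign"],
            sim_bundle["orthologs"],
            sim_bundle["organ"],
            sim_bundle["localization"],
            RunConfig(),
        )
        assert again == pipeline_result.funnel

    def test_permissive_filters_reduce_to_top_n_truth_overlap(self, sim_bundle,
                                                              pipeline_result):
        """With lossless external sets and every filter permissive, the final
        output is just the top-N candidates that are planted AT1 markers
        surviving conservation (the lossless limit)."""
        truth = sim_bundle["truth"]
        permissive = RunConfig(
            specificity_fold=0.0, specificity_floor=0.0,
            allowed_localizations=("plasma-membrane", "nuclear", "cytoplasm",
                                   "other"),
            unknown_localization_policy="keep",
        )
        funnel = run_funnel(
            pipeline_result.marker_tables[pipeline_result.target_cluster],
            sim_bundle["external"],
            sim_bundle["foreign"],
            sim_bundle["orthologs"],
            sim_bundle["organ"],
            sim_bundle["localization"],
            permissive,
        )
        conserved = {
            g.casefold()
            for g, f in truth.gene_flags.items()
            if "conserved" in f
        }
        top = funnel.stages[0].input_set.canonical()
        assert funnel.final_set.canonical() == top & conserved

    def test_final_ranking_ordered_by_fold_then_p(self, pipeline_result):
        ranking = pipeline_result.funnel.final_ranking
        folds = [r[1] for r in ranking]
        assert folds == sorted(folds, reverse=True)

    def test_report_round_trip(self, tmp_path, pipeline_result):
        p = tmp_path / "funnel.json"
        write_funnel_report(pipeline_result.funnel, p)
        assert read_funnel_report(p) == pipeline_result.funnel

    def test_empty_final_stage_reported_without_error(self, tmp_path,
                                                      pipeline_result, sim_bundle):
        strict = RunConfig(allowed_localizations=("mitochondrial",))
        funnel = run_funnel(
            pipeline_result.marker_tables[pipeline_result.target_cluster],
            sim_bundle["external"], sim_bundle["foreign"],
            sim_bundle["orthologs"], sim_bundle["organ"],
            sim_bundle["localization"], strict,
        )
        assert len(funnel.final_set) == 0
        p = tmp_path / "empty.json"
        write_funnel_report(funnel, p)
        assert read_funnel_report(p) == funnel
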