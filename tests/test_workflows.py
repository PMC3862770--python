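import json

import pytest

import genassoc_meta as gm
from genassoc_meta._format import format_het, format_or_ci_p, format_p
from genassoc_meta.exceptions import InsufficientStudiesError


def est(y, se, sid, year=2000, **cov):
    return gm.EffectEstimate(log_or=y, se=se, study_id=sid,
                             model=gm.GeneticModel.ALLELE,
                             covariates={"year": year, **cov})


class TestSubgroups:
    def test_k_values_sum_to_overall(self, allele_estimates):
        for axis in ("ethnicity", "study_size"):
            spec = gm.SubgroupSpec(axis=axis, size_threshold=1000)
            groups = gm.subgroup_analysis(allele_estimates, spec)
            assert sum(r.k for r in groups.values()) == len(allele_estimates)

    def test_single_subgroup_equals_overall(self, allele_estimates):
        spec = gm.SubgroupSpec(axis="intervention")
        groups = gm.subgroup_analysis(allele_estimates, spec)
        assert set(groups) == {"stent"}
        overall = gm.pool_random_dl(allele_estimates)
        assert groups["stent"].pooled_log_or == overall.pooled_log_or

    def test_size_threshold_boundary_is_large(self):
        ests = [est(0.1, 0.2, "a", size=500), est(0.2, 0.2, "b", size=499)]
        groups = gm.subgroup_analysis(ests, gm.SubgroupSpec("study_size", 500))
        assert groups["large"].k == 1 and groups["small"].k == 1

    def test_missing_axis_goes_to_unknown(self):
        ests = [est(0.1, 0.2, "a", ethnicity="Asian"), est(0.2, 0.2, "b")]
        groups = gm.subgroup_analysis(ests, gm.SubgroupSpec("ethnicity"))
        assert set(groups) == {"Asian", "unknown"}


class TestCumulative:
    def test_same_year_studies_enter_together(self):
        ests = [est(0.1, 0.2, "a", 1995), est(0.2, 0.2, "b", 1995),
                est(0.3, 0.2, "c", 1999)]
        steps = gm.cumulative_meta(ests)
        assert [(s.year, s.k_so_far) for s in steps] == [(1995, 2), (1999, 3)]

    def test_final_step_equals_overall_for_all_models(self, sim_cohort):
        for model in gm.GENETIC_MODELS:
            ests, _ = gm.effects_from_records(sim_cohort, model)
            steps = gm.cumulative_meta(ests)
            overall = gm.pool_random_dl(ests)
            final = steps[-1].pooled
            assert final.k == overall.k
            assert final.pooled_log_or == pytest.approx(
                overall.pooled_log_or, rel=1e-12)
            assert final.tau2 == pytest.approx(overall.tau2, rel=1e-12, abs=1e-15)

    def test_single_year_single_step(self):
        ests = [est(0.1, 0.2, "a", 2001), est(0.3, 0.2, "b", 2001)]
        steps = gm.cumulative_meta(ests)
        assert len(steps) == 1 and steps[0].k_so_far == 2


class TestLeaveOneOut:
    def test_k_rows_each_pooling_k_minus_one(self, allele_estimates):
        rows = gm.leave_one_out(allele_estimates)
        assert len(rows) == len(allele_estimates)
        assert all(r.pooled.k == len(allele_estimates) - 1 for r in rows)
        assert {r.omitted_study_id for r in rows} == \
            {e.study_id for e in allele_estimates}

    def test_near_zero_weight_study_changes_nothing(self):
        ests = [est(0.1, 0.2, "a"), est(0.3, 0.25, "b"), est(0.2, 0.15, "c"),
                est(5.0, 1e4, "ghost")]  # essentially no weight
        rows = {r.omitted_study_id: r.pooled for r in gm.leave_one_out(ests)}
        full = gm.pool_random_dl(ests)
        assert rows["ghost"].pooled_log_or == pytest.approx(
            full.pooled_log_or, abs=1e-6)

    def test_single_study_errors(self):
        with pytest.raises(InsufficientStudiesError):
            gm.leave_one_out([est(0.1, 0.2, "a")])


class TestFormatting:
    def test_or_ci_p_cell_shape(self):
        assert format_or_ci_p(1.31, 1.08, 1.58, 0.006) == "1.31 (1.08-1.58); 0.006"

    def test_small_p_threshold_format(self):
        assert format_p(9e-5) == "<10^-4"
        assert format_p(0.0001) == "0.0001"

    def test_het_cell(self):
        assert format_het(5e-5, 79.0) == "<10^-4; 79%"


class TestRunFullAnalysis:
    def test_report_covers_all_models_and_strata(self, sim_cohort):
        report = gm.run_full_analysis(sim_cohort)
        assert set(report["strata"]) == {"stent"}
        models = report["strata"]["stent"]["models"]
        assert set(models) == {m.value for m in gm.GENETIC_MODELS}
        for entry in models.values():
            assert entry["overall"]["k"] == len(sim_cohort)
            axes = entry["subgroups"]
            for axis_groups in axes.values():
                assert sum(g["k"] for g in axis_groups.values()) == len(sim_cohort)

    def test_single_study_cohort(self, sim_cohort):
        report = gm.run_full_analysis(sim_cohort[:1])
        for model in gm.GENETIC_MODELS:
            entry = report["strata"]["stent"]["models"][model.value]
            ests, _ = gm.effects_from_records(sim_cohort[:1], model)
            assert entry["overall"]["pooled_or"] == pytest.approx(
                ests[0].odds_ratio)

    def test_determinism_byte_identical(self, sim_cohort):
        r1 = gm.run_full_analysis(sim_cohort)
        r2 = gm.run_full_analysis(sim_cohort)
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)

    def test_report_cells_match_table_style(self, sim_cohort):
        report = gm.run_full_analysis(sim_cohort)
        cell = report["strata"]["stent"]["models"]["allele"]["overall"]
        import re
        assert re.fullmatch(
            r"\d+\.\d{2} \(\d+\.\d{2}-\d+\.\d{2}\); (<10\^-4|[\d.eE+-]+)",
            cell["or_ci_p"])

    def test_write_report_files(self, sim_cohort, tmp_path):
        report = gm.run_full_analysis(sim_cohort)
        written = gm.write_report(report, tmp_path)
        names = {p.name for p in written}
        assert "report.json" in names and "pooled_stent.tsv" in names
        assert "cumulative_stent.tsv" in names and "loo_stent.tsv" in names
        pooled = (tmp_path / "pooled_stent.tsv").read_text().splitlines()
        assert pooled[0].split("\t") == ["model", "subgroup_axis", "subgroup",
                                         "k", "or_ci_p", "het"]

    def test_ace_inhibitor_stratified_pooling(self):
        records = gm.simulate_studies(gm.SimulationConfig(k_studies=6, seed=3))
        from dataclasses import replace
        records = [replace(r, ace_inhibitor_stratum="treated" if i % 2 else "untreated")
                   for i, r in enumerate(records)]
        ests, _ = gm.effects_from_records(records, gm.GeneticModel.RECESSIVE)
        groups = gm.subgroup_analysis(ests, gm.SubgroupSpec("ace_inhibitor"))
        assert set(groups) == {"treated", "untreated"}
        assert sum(g.k for g in groups.values()) == 6
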