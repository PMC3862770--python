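"""Orchestration: the full per-stratum meta-analysis and its companion analyses.

``run_full_analysis`` pools every genetic contrast within each intervention
stratum (random effects throughout — with no heterogeneity the estimator
degenerates to the fixed-effect one), runs subgroup analyses, cumulative
meta-analysis by publication year, leave-one-out sensitivity analysis and
the bias diagnostics, and emits one JSON-serializable report whose cells
use the conventional "OR (low-high); P" / "P(Q); I2%" formats.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .config import AnalysisConfig
from .contrasts import (EffectEstimate, GENETIC_MODELS, GeneticModel,
                        effects_from_records)
from .exceptions import InsufficientStudiesError, SingularDesignError
from .bias_diagnostics import begg_test, egger_test, funnel_to_tsv
from .metareg import meta_regress
from .pooling import (MetaAnalysis, PooledResult, classify_heterogeneity,
                      pool_random_dl)
from .study_io import StudyRecord, apply_inclusion_filters


@dataclass(frozen=True)
class SubgroupSpec:
    """One stratification axis; every study maps to exactly one subgroup."""

    axis: str  # ethnicity | study_size | intervention | ace_inhibitor
    size_threshold: int = 500

    def subgroup_of(self, estimate: EffectEstimate) -> str:
        cov = estimate.covariates
        if self.axis == "ethnicity":
            return cov.get("ethnicity") or "unknown"
        if self.axis == "study_size":
            size = cov.get("size")
            if size is None:
                return "unknown"
            return "large" if size >= self.size_threshold else "small"
        if self.axis == "intervention":
            return cov.get("intervention") or "unknown"
        if self.axis == "ace_inhibitor":
            return cov.get("ace_inhibitor_stratum") or "unstratified"
        raise ValueError(f"unknown subgroup axis {self.axis!r}")


@dataclass(frozen=True)
class CumulativeStep:
    year: int
    k_so_far: int
    pooled: PooledResult


@dataclass(frozen=True)
class LeaveOneOutRow:
    omitted_study_id: str
    pooled: PooledResult


def subgroup_analysis(estimates: Sequence[EffectEstimate],
                      spec: SubgroupSpec) -> dict[str, PooledResult]:
    """Pool independently within each subgroup along one axis.

    Subgroup k values always sum to the overall k (an estimate with a
    missing axis value lands in subgroup ``"unknown"``).
    """
    groups: dict[str, list[EffectEstimate]] = {}
    for e in estimates:
        groups.setdefault(spec.subgroup_of(e), []).append(e)
    return {name: pool_random_dl(members)
            for name, members in sorted(groups.items())}


def cumulative_meta(estimates: Sequence[EffectEstimate],
                    method: str = "random") -> list[CumulativeStep]:
    """Chronological re-pooling at the end of each publication year.

    Studies are ordered by year; all same-year studies enter together, so
    there is one step per distinct year and the final step reproduces the
    overall pooled result. Estimates without a year are excluded (their ids
    are discoverable by comparing k_so_far with len(estimates)).
    """
    dated = [e for e in estimates if e.covariates.get("year") is not None]
    if not dated:
        raise ValueError("cumulative meta-analysis requires publication years")
    dated.sort(key=lambda e: (e.covariates["year"], e.study_id))
    steps: list[CumulativeStep] = []
    so_far: list[EffectEstimate] = []
    years = sorted({e.covariates["year"] for e in dated})
    idx = 0
    for year in years:
        while idx < len(dated) and dated[idx].covariates["year"] == year:
            so_far.append(dated[idx])
            idx += 1
        steps.append(CumulativeStep(
            year=int(year), k_so_far=len(so_far),
            pooled=MetaAnalysis.from_estimates(so_far).fit(method=method)))
    return steps


def leave_one_out(estimates: Sequence[EffectEstimate],
                  method: str = "random") -> list[LeaveOneOutRow]:
    """Re-pool k times, omitting one study each time (k >= 2 required)."""
    ests = list(estimates)
    if len(ests) < 2:
        raise InsufficientStudiesError("leave-one-out needs k >= 2")
    rows = []
    for i, omitted in enumerate(ests):
        rest = ests[:i] + ests[i + 1:]
        rows.append(LeaveOneOutRow(
            omitted_study_id=omitted.study_id,
            pooled=MetaAnalysis.from_estimates(rest).fit(method=method)))
    return rows


# ---------------------------------------------------------------------
# full pipeline


def _pooled_cell(result: PooledResult, alpha: float) -> dict:
    verdict = classify_heterogeneity(result, alpha)
    d = result.to_dict()
    d["or_ci_p"] = result.or_ci_p()
    d["het"] = result.het_cell()
    d["het_significant"] = verdict.significant
    d["het_band"] = verdict.band
    return d


def run_full_analysis(records: Sequence[StudyRecord],
                      config: AnalysisConfig | None = None) -> dict:
    """The complete analysis over validated study records.

    Applies the inclusion filters, then per intervention stratum and per
    genetic contrast: overall random-effects pooling with heterogeneity
    verdict and subgroup analyses; per stratum (on the allele contrast,
    the headline per-allele effect): bias diagnostics, meta-regression on
    the configured moderators, cumulative meta-analysis, leave-one-out
    sensitivity analysis and forest/funnel data. Deterministic: identical
    input and config give an identical report.
    """
    config = config or AnalysisConfig()
    filtered = apply_inclusion_filters(
        records, config.followup_window,
        exclude_hwe_violations=config.exclude_hwe_violations)
    report: dict = {
        "config": config.to_dict(),
        "n_input_records": len(records),
        "excluded": [{"study_id": rec.study_id, "reason": reason}
                     for rec, reason in filtered.dropped],
        "strata": {},
    }
    strata: dict[str, list[StudyRecord]] = {}
    for rec in filtered.kept:
        strata.setdefault(rec.intervention, []).append(rec)
    for stratum in sorted(strata):
        recs = strata[stratum]
        entry: dict = {"n_datasets": len(recs), "models": {}}
        for model in GENETIC_MODELS:
            estimates, skipped = effects_from_records(
                recs, model, config.continuity_constant)
            mod_entry: dict = {"skipped": [
                {"study_id": sid, "reason": why} for sid, why in skipped]}
            if not estimates:
                mod_entry["overall"] = None
            else:
                overall = pool_random_dl(estimates)
                mod_entry["overall"] = _pooled_cell(overall, config.heterogeneity_alpha)
                mod_entry["subgroups"] = {}
                for axis in config.subgroup_axes:
                    spec = SubgroupSpec(axis=axis,
                                        size_threshold=config.size_threshold)
                    mod_entry["subgroups"][axis] = {
                        name: _pooled_cell(res, config.heterogeneity_alpha)
                        for name, res in subgroup_analysis(estimates, spec).items()}
            entry["models"][model.value] = mod_entry
        # companion analyses on the headline per-allele contrast
        allele_ests, _ = effects_from_records(
            recs, GeneticModel.ALLELE, config.continuity_constant)
        entry["allele_companions"] = _companions(allele_ests, config)
        report["strata"][stratum] = entry
    return report


def _companions(estimates: list[EffectEstimate],
                config: AnalysisConfig) -> dict:
    out: dict = {}
    if not estimates:
        return out
    try:
        egg = egger_test(estimates)
        out["egger"] = {"intercept": egg.intercept, "se": egg.intercept_se,
                        "t": egg.t, "df": egg.df, "p": egg.p}
    except (InsufficientStudiesError, SingularDesignError) as exc:
        out["egger"] = {"error": str(exc)}
    try:
        begg = begg_test(estimates)
        out["begg"] = {"kendall_tau": begg.kendall_tau, "p": begg.p}
    except InsufficientStudiesError as exc:
        out["begg"] = {"error": str(exc)}
    out["meta_regression"] = {}
    for moderator in config.moderators:
        try:
            fit = meta_regress(estimates, moderator)
            out["meta_regression"][moderator] = {
                "beta1": fit.beta1, "se1": fit.se1, "p": fit.p_beta1,
                "tau2_resid": fit.tau2_resid, "k": fit.k,
                "dropped": list(fit.dropped)}
        except InsufficientStudiesError as exc:
            out["meta_regression"][moderator] = {"error": str(exc)}
    out["cumulative"] = [
        {"year": s.year, "k_so_far": s.k_so_far,
         "or_ci_p": s.pooled.or_ci_p(), "pooled_or": s.pooled.pooled_or,
         "ci95_low": s.pooled.ci95[0], "ci95_high": s.pooled.ci95[1]}
        for s in cumulative_meta(estimates)]
    if len(estimates) >= 2:
        out["leave_one_out"] = [
            {"omitted": row.omitted_study_id, "or_ci_p": row.pooled.or_ci_p(),
             "pooled_or": row.pooled.pooled_or,
             "ci95_low": row.pooled.ci95[0], "ci95_high": row.pooled.ci95[1]}
            for row in leave_one_out(estimates)]
    overall = pool_random_dl(estimates)
    out["forest"] = [
        {"study_id": e.study_id, "or": e.odds_ratio,
         "ci95_low": math.exp(e.log_or - 1.959964 * e.se),
         "ci95_high": math.exp(e.log_or + 1.959964 * e.se),
         "weight_pct": 100.0 * overall.weights[e.study_id]}
        for e in estimates]
    return out


# ---------------------------------------------------------------------
# serialization


def write_report(report: dict, outdir, estimates_by_stratum=None) -> list[Path]:
    """Write report.json plus flat TSV views; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    written.append(path)

    for stratum, entry in report["strata"].items():
        path = outdir / f"pooled_{stratum}.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("model\tsubgroup_axis\tsubgroup\tk\tor_ci_p\thet\n")
            for model, mod_entry in entry["models"].items():
                cell = mod_entry.get("overall")
                if cell is None:
                    continue
                fh.write(f"{model}\toverall\toverall\t{cell['k']}"
                         f"\t{cell['or_ci_p']}\t{cell['het']}\n")
                for axis, groups in mod_entry.get("subgroups", {}).items():
                    for name, sub in groups.items():
                        fh.write(f"{model}\t{axis}\t{name}\t{sub['k']}"
                                 f"\t{sub['or_ci_p']}\t{sub['het']}\n")
        written.append(path)

        comp = entry.get("allele_companions", {})
        for key, fname, cols in (
                ("cumulative", f"cumulative_{stratum}.tsv",
                 ("year", "k_so_far", "pooled_or", "ci95_low", "ci95_high")),
                ("leave_one_out", f"loo_{stratum}.tsv",
                 ("omitted", "pooled_or", "ci95_low", "ci95_high")),
                ("forest", f"forest_{stratum}.tsv",
                 ("study_id", "or", "ci95_low", "ci95_high", "weight_pct"))):
            rows = comp.get(key)
            if not rows:
                continue
            path = outdir / fname
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("\t".join(cols) + "\n")
                for row in rows:
                    fh.write("\t".join(_fmt(row[c]) for c in cols) + "\n")
            written.append(path)
    return written


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
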