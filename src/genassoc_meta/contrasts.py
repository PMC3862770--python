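"""Genetic-model contrasts: 2x2 tables and per-study log odds ratios.

For a biallelic insertion/deletion variant with genotypes II, ID, DD the
five standard contrasts of the candidate-gene literature are supported:

========================  ============================  ============================
model                     "exposed"                     "unexposed"
========================  ============================  ============================
allele                    D alleles (2*DD + ID)         I alleles (2*II + ID)
dominant                  DD + ID carriers              II
recessive                 DD                            ID + II
heterozygous              ID                            II   (DD discarded)
homozygous                DD                            II   (ID discarded)
========================  ============================  ============================

The allele contrast counts two alleles per person and ignores within-person
allele dependence — the standard per-allele odds ratio approximation.
Effects are unadjusted log odds ratios with Woolf variances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

from .exceptions import EligibilityError, NonInformativeStudyError
from .study_io import StudyRecord


class GeneticModel(str, Enum):
    ALLELE = "allele"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"

    def __str__(self) -> str:  # keeps report/TSV cells clean
        return self.value


GENETIC_MODELS = tuple(GeneticModel)


@dataclass(frozen=True)
class ContrastTable:
    """2x2 exposure-by-outcome table for one study under one genetic model.

    Cells follow the epidemiological convention: ``a`` exposed cases,
    ``b`` unexposed cases, ``c`` exposed controls, ``d`` unexposed controls.
    Cells are reals because a continuity correction may have been applied
    (``corrected`` records whether it was).
    """

    a: float
    b: float
    c: float
    d: float
    model: GeneticModel
    study_id: str
    corrected: bool = False

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class EffectEstimate:
    """Log odds ratio and Woolf standard error for one study/model."""

    log_or: float
    se: float
    study_id: str
    model: GeneticModel
    covariates: dict = field(default_factory=dict, compare=False)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)

    @property
    def variance(self) -> float:
        return self.se ** 2


def _split(ii: int, id_: int, dd: int, model: GeneticModel) -> tuple[int, int]:
    """(exposed, unexposed) counts for one arm under a genetic model."""
    if model is GeneticModel.ALLELE:
        return 2 * dd + id_, 2 * ii + id_
    if model is GeneticModel.DOMINANT:
        return dd + id_, ii
    if model is GeneticModel.RECESSIVE:
        return dd, id_ + ii
    if model is GeneticModel.HETEROZYGOUS:
        return id_, ii
    if model is GeneticModel.HOMOZYGOUS:
        return dd, ii
    raise ValueError(f"unknown genetic model {model!r}")


def build_contrast(record: StudyRecord, model: GeneticModel) -> ContrastTable:
    """Collapse a study's genotype (or allele) counts under one genetic model.

    Allele-only records are eligible for the allele contrast only; the four
    genotype-based models need the full genotype distribution.
    """
    model = GeneticModel(model)
    full = record.has_genotypes("case") and record.has_genotypes("ctrl")
    if not full:
        if model is not GeneticModel.ALLELE or not (
                record.has_alleles("case") and record.has_alleles("ctrl")):
            raise EligibilityError(
                f"{record.study_id}: genotype counts required for the "
                f"{model.value} model are not available")
        i_case, d_case = record.allele_counts("case")
        i_ctrl, d_ctrl = record.allele_counts("ctrl")
        a, b, c, d = d_case, i_case, d_ctrl, i_ctrl
    else:
        a, b = _split(record.n_case_II, record.n_case_ID, record.n_case_DD, model)
        c, d = _split(record.n_ctrl_II, record.n_ctrl_ID, record.n_ctrl_DD, model)
    return ContrastTable(a=float(a), b=float(b), c=float(c), d=float(d),
                         model=model, study_id=record.study_id)


def continuity_correct(table: ContrastTable, constant: float = 0.5) -> ContrastTable:
    """Haldane-Anscombe correction: add ``constant`` to all four cells if any is zero.

    Applied per affected table only, not to every study. A table with all
    four cells zero carries no information and raises
    :class:`NonInformativeStudyError` so callers can exclude it with a
    diagnostic instead of fabricating an effect.
    """
    if constant <= 0:
        raise ValueError("continuity constant must be positive")
    cells = table.cells
    if all(x == 0 for x in cells):
        raise NonInformativeStudyError(
            f"{table.study_id}: all cells zero under {table.model.value} model")
    if min(cells) > 0:
        return table
    return replace(table, a=table.a + constant, b=table.b + constant,
                   c=table.c + constant, d=table.d + constant, corrected=True)


def estimate_effect(table: ContrastTable) -> EffectEstimate:
    """Woolf log odds ratio: ``ln(ad/bc)`` with variance ``1/a+1/b+1/c+1/d``."""
    a, b, c, d = table.cells
    if min(a, b, c, d) <= 0:
        raise ValueError(
            f"{table.study_id}: zero cell reached estimate_effect; "
            "apply continuity_correct first")
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(log_or=log_or, se=se, study_id=table.study_id,
                          model=table.model)


def effect_from_record(record: StudyRecord, model: GeneticModel,
                       correction: float = 0.5) -> EffectEstimate:
    """build_contrast -> continuity_correct -> estimate_effect for one record.

    The returned estimate carries the study-level covariates used downstream
    by subgroup analysis and meta-regression.
    """
    table = continuity_correct(build_contrast(record, model), correction)
    est = estimate_effect(table)
    covariates = {
        "year": record.year,
        "ethnicity": record.ethnicity,
        "intervention": record.intervention,
        "size": record.total_n,
        "followup": record.followup_months,
        "age": record.mean_age,
        "pct_male": record.pct_male,
        "ace_inhibitor_stratum": record.ace_inhibitor_stratum,
    }
    return replace(est, covariates=covariates)


def effects_from_records(
    records: Sequence[StudyRecord],
    model: GeneticModel,
    correction: float = 0.5,
) -> tuple[list[EffectEstimate], list[tuple[str, str]]]:
    """Per-study effects for every eligible record.

    Returns ``(estimates, skipped)`` where ``skipped`` pairs a study id with
    the reason it contributed no estimate (``"ineligible"`` for allele-only
    records under a genotype model, ``"non_informative"`` for all-zero
    tables).
    """
    estimates, skipped = [], []
    for rec in records:
        try:
            estimates.append(effect_from_record(rec, model, correction))
        except EligibilityError:
            skipped.append((rec.study_id, "ineligible"))
        except NonInformativeStudyError:
            skipped.append((rec.study_id, "non_informative"))
    return estimates, skipped


def tables_to_tsv(tables: Sequence[ContrastTable], path) -> None:
    """Serialize contrast tables to TSV (study_id, model, a, b, c, d, corrected)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("study_id\tmodel\ta\tb\tc\td\tcorrected\n")
        for t in tables:
            fh.write(f"{t.study_id}\t{t.model.value}\t{t.a:g}\t{t.b:g}"
                     f"\t{t.c:g}\t{t.d:g}\t{str(t.corrected).lower()}\n")
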