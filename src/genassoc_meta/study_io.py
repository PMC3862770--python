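"""Reading, validating and summarising study-characteristics tables.

A *study record* is one dataset of a genetic-association cohort: metadata
(publication year, ethnicity group, intervention type, follow-up duration,
quality label) plus genotype counts (II, ID, DD) for restenosis cases and
controls — or allele counts (I, D) when a publication reports only those.

The module applies the inclusion filters used in restenosis meta-analyses
(an angiographic follow-up window, presence of usable counts) and tests
consistency of control genotype frequencies with Hardy-Weinberg equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .exceptions import SchemaError, ValidationError

ETHNICITIES = ("Asian", "Caucasian", "Other")
INTERVENTIONS = ("stent", "balloon")
QUALITY_LABELS = ("High", "Median", "Poor")
ACE_STRATA = ("treated", "untreated", "unstratified")

#: columns that must be present in any studies CSV
MANDATORY_COLUMNS = ("study_id", "year", "ethnicity", "intervention")

#: optional columns; absent columns are read as all-missing
OPTIONAL_COLUMNS = (
    "followup_months",
    "restenosis_definition",
    "n_case_II", "n_case_ID", "n_case_DD",
    "n_ctrl_II", "n_ctrl_ID", "n_ctrl_DD",
    "a_case_I", "a_case_D", "a_ctrl_I", "a_ctrl_D",
    "n_cases_total", "n_controls_total",
    "mean_age", "pct_male", "quality", "ace_inhibitor_stratum",
)

_COUNT_FIELDS = (
    "n_case_II", "n_case_ID", "n_case_DD",
    "n_ctrl_II", "n_ctrl_ID", "n_ctrl_DD",
    "a_case_I", "a_case_D", "a_ctrl_I", "a_ctrl_D",
    "n_cases_total", "n_controls_total",
)


@dataclass
class StudyRecord:
    """One dataset's metadata and genotype/allele counts.

    Counts are ``None`` when the source publication does not report them;
    missing is never silently coerced to zero.
    """

    study_id: str
    year: int
    ethnicity: str
    intervention: str
    followup_months: float | None = None
    restenosis_definition: str | None = None
    n_case_II: int | None = None
    n_case_ID: int | None = None
    n_case_DD: int | None = None
    n_ctrl_II: int | None = None
    n_ctrl_ID: int | None = None
    n_ctrl_DD: int | None = None
    a_case_I: int | None = None
    a_case_D: int | None = None
    a_ctrl_I: int | None = None
    a_ctrl_D: int | None = None
    n_cases_total: int | None = None
    n_controls_total: int | None = None
    mean_age: float | None = None
    pct_male: float | None = None
    quality: str | None = None
    ace_inhibitor_stratum: str = "unstratified"
    hwe_warning: bool = field(default=False, compare=False)

    # -- derived views -------------------------------------------------

    def has_genotypes(self, arm: str) -> bool:
        trio = self._genotype_trio(arm)
        return all(v is not None for v in trio)

    def has_alleles(self, arm: str) -> bool:
        pre = "a_case" if arm == "case" else "a_ctrl"
        return (getattr(self, pre + "_I") is not None
                and getattr(self, pre + "_D") is not None)

    def _genotype_trio(self, arm: str):
        pre = "n_case" if arm == "case" else "n_ctrl"
        return tuple(getattr(self, f"{pre}_{g}") for g in ("II", "ID", "DD"))

    def allele_counts(self, arm: str) -> tuple[int, int]:
        """(I, D) allele counts for an arm, derived from genotypes when present."""
        if self.has_genotypes(arm):
            ii, id_, dd = self._genotype_trio(arm)
            return 2 * ii + id_, 2 * dd + id_
        if self.has_alleles(arm):
            pre = "a_case" if arm == "case" else "a_ctrl"
            return getattr(self, pre + "_I"), getattr(self, pre + "_D")
        raise ValueError(f"{self.study_id}: no counts for arm {arm!r}")

    @property
    def n_cases(self) -> int | None:
        if self.has_genotypes("case"):
            return sum(self._genotype_trio("case"))
        if self.has_alleles("case"):
            return (self.a_case_I + self.a_case_D) // 2
        return self.n_cases_total

    @property
    def n_controls(self) -> int | None:
        if self.has_genotypes("ctrl"):
            return sum(self._genotype_trio("ctrl"))
        if self.has_alleles("ctrl"):
            return (self.a_ctrl_I + self.a_ctrl_D) // 2
        return self.n_controls_total

    @property
    def total_n(self) -> int | None:
        if self.n_cases is None or self.n_controls is None:
            return None
        return self.n_cases + self.n_controls

    def has_any_counts(self) -> bool:
        return ((self.has_genotypes("case") and self.has_genotypes("ctrl"))
                or (self.has_alleles("case") and self.has_alleles("ctrl")))

    # -- validation ----------------------------------------------------

    def problems(self) -> list[str]:
        """Invariant violations, as human-readable strings (empty when valid)."""
        out = []
        sid = self.study_id
        if self.ethnicity not in ETHNICITIES:
            out.append(f"{sid}: ethnicity {self.ethnicity!r} not in {ETHNICITIES}")
        if self.intervention not in INTERVENTIONS:
            out.append(f"{sid}: intervention {self.intervention!r} not in {INTERVENTIONS}")
        if self.quality is not None and self.quality not in QUALITY_LABELS:
            out.append(f"{sid}: quality {self.quality!r} not in {QUALITY_LABELS}")
        if self.ace_inhibitor_stratum not in ACE_STRATA:
            out.append(f"{sid}: ace_inhibitor_stratum {self.ace_inhibitor_stratum!r} invalid")
        for name in _COUNT_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                out.append(f"{sid}: negative count {name}={v}")
        for arm in ("case", "ctrl"):
            trio = self._genotype_trio(arm)
            present = [v is not None for v in trio]
            if any(present) and not all(present):
                out.append(f"{sid}: partial genotype counts in arm {arm!r}")
            pre = "a_case" if arm == "case" else "a_ctrl"
            al = (getattr(self, pre + "_I"), getattr(self, pre + "_D"))
            if (al[0] is None) != (al[1] is None):
                out.append(f"{sid}: partial allele counts in arm {arm!r}")
            # declared allele counts must agree with genotype-derived ones
            if all(present) and all(v is not None for v in al):
                ii, id_, dd = trio
                if al != (2 * ii + id_, 2 * dd + id_):
                    out.append(f"{sid}: allele counts inconsistent with genotypes in arm {arm!r}")
        if (self.n_cases_total is not None and self.has_genotypes("case")
                and sum(self._genotype_trio("case")) != self.n_cases_total):
            out.append(f"{sid}: genotype case counts do not sum to declared case total")
        if (self.n_controls_total is not None and self.has_genotypes("ctrl")
                and sum(self._genotype_trio("ctrl")) != self.n_controls_total):
            out.append(f"{sid}: genotype control counts do not sum to declared control total")
        if self.followup_months is not None and self.followup_months <= 0:
            out.append(f"{sid}: followup_months must be positive")
        if self.pct_male is not None and not (0 <= self.pct_male <= 100):
            out.append(f"{sid}: pct_male outside [0, 100]")
        return out


@dataclass(frozen=True)
class CohortSummary:
    """Totals for a validated study collection."""

    n_studies: int
    n_datasets: int
    total_cases: int
    total_controls: int
    total_patients: int
    counts_by_quality: dict
    counts_by_intervention: dict  # label -> (cases, controls)


@dataclass(frozen=True)
class HWEResult:
    """Goodness-of-fit of genotype counts to Hardy-Weinberg proportions."""

    chi2: float
    df: int
    p_value: float
    allele_freq_D: float


@dataclass(frozen=True)
class FilterResult:
    kept: list
    dropped: list  # (StudyRecord, reason) pairs


# ---------------------------------------------------------------------
# loading / writing


def _parse_cell(raw: str):
    s = raw.strip()
    if s == "" or s == "NA":
        return None
    return s


def _to_int(value, what: str, sid: str, out: list):
    if value is None:
        return None
    try:
        f = float(value)
        if not f.is_integer():
            raise ValueError
        return int(f)
    except ValueError:
        out.append(f"{sid}: {what}={value!r} is not an integer")
        return None


def _to_float(value, what: str, sid: str, out: list):
    if value is None:
        return None
    try:
        return float(value)
    except ValueError:
        out.append(f"{sid}: {what}={value!r} is not a number")
        return None


def load_studies(path, *, hwe_alpha: float = 0.05) -> list[StudyRecord]:
    """Load study records from a CSV file.

    The file must be UTF-8, comma-separated, with a header row carrying at
    least :data:`MANDATORY_COLUMNS`; missing values are empty cells or
    ``NA``. Rows violating the record invariants are collected and raised
    together as a :class:`ValidationError` with row-level diagnostics.

    Controls of genotype-complete records are tested for Hardy-Weinberg
    equilibrium; deviation at ``hwe_alpha`` sets ``hwe_warning`` on the
    record (it is never an exclusion by itself).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns
               if c not in MANDATORY_COLUMNS and c not in OPTIONAL_COLUMNS]
    if unknown:
        raise SchemaError(f"unrecognised column(s): {', '.join(unknown)}")

    records, problems = [], []
    for idx, row in df.iterrows():
        cells = {c: _parse_cell(row[c]) for c in df.columns}
        sid = cells.get("study_id") or f"row {idx + 2}"
        row_problems: list[str] = []
        if cells.get("study_id") is None:
            row_problems.append(f"row {idx + 2}: missing study_id")
        year = _to_int(cells.get("year"), "year", sid, row_problems)
        if year is None and not row_problems:
            row_problems.append(f"{sid}: missing year")
        kw = {}
        for name in _COUNT_FIELDS:
            kw[name] = _to_int(cells.get(name), name, sid, row_problems)
        rec = StudyRecord(
            study_id=sid,
            year=year if year is not None else -1,
            ethnicity=cells.get("ethnicity") or "",
            intervention=cells.get("intervention") or "",
            followup_months=_to_float(cells.get("followup_months"),
                                      "followup_months", sid, row_problems),
            restenosis_definition=cells.get("restenosis_definition"),
            mean_age=_to_float(cells.get("mean_age"), "mean_age", sid, row_problems),
            pct_male=_to_float(cells.get("pct_male"), "pct_male", sid, row_problems),
            quality=cells.get("quality"),
            ace_inhibitor_stratum=cells.get("ace_inhibitor_stratum") or "unstratified",
            **kw,
        )
        row_problems.extend(rec.problems())
        if row_problems:
            problems.extend(row_problems)
            continue
        if rec.has_genotypes("ctrl"):
            hwe = hwe_test(rec.n_ctrl_II, rec.n_ctrl_ID, rec.n_ctrl_DD)
            if hwe.p_value < hwe_alpha:
                rec = replace(rec, hwe_warning=True)
        records.append(rec)
    if problems:
        raise ValidationError(problems)
    return records


def write_studies(records: Iterable[StudyRecord], path) -> None:
    """Write records to CSV in the same dialect :func:`load_studies` reads."""
    cols = [f.name for f in fields(StudyRecord) if f.name != "hwe_warning"]
    rows = []
    for rec in records:
        rows.append({c: ("" if getattr(rec, c) is None else getattr(rec, c))
                     for c in cols})
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------
# filters and summaries


def apply_inclusion_filters(
    records: Sequence[StudyRecord],
    window_months: tuple[float, float] = (3.0, 12.0),
    *,
    require_counts: bool = True,
    exclude_hwe_violations: bool = False,
) -> FilterResult:
    """Partition records into kept and dropped-with-reason.

    Restenosis is a time-related endpoint, so records whose angiographic
    follow-up falls outside ``window_months`` are dropped (records with no
    recorded follow-up pass). With ``require_counts``, records carrying
    neither genotype nor allele counts are dropped with reason
    ``"no_counts"``. Filtering is total: no record raises.
    """
    lo, hi = window_months
    if not (lo <= hi):
        raise ValueError(f"invalid follow-up window {window_months}")
    kept, dropped = [], []
    for rec in records:
        if rec.followup_months is not None and not (lo <= rec.followup_months <= hi):
            dropped.append((rec, "followup_window"))
        elif require_counts and not rec.has_any_counts():
            dropped.append((rec, "no_counts"))
        elif exclude_hwe_violations and rec.hwe_warning:
            dropped.append((rec, "hwe_violation"))
        else:
            kept.append(rec)
    return FilterResult(kept=kept, dropped=dropped)


def summarize_cohort(records: Sequence[StudyRecord]) -> CohortSummary:
    """Tally datasets, patients, quality labels and per-intervention totals."""
    by_quality: dict[str, int] = {}
    by_intervention: dict[str, tuple[int, int]] = {}
    total_cases = total_controls = 0
    for rec in records:
        cases = rec.n_cases or 0
        controls = rec.n_controls or 0
        total_cases += cases
        total_controls += controls
        if rec.quality is not None:
            by_quality[rec.quality] = by_quality.get(rec.quality, 0) + 1
        c0, c1 = by_intervention.get(rec.intervention, (0, 0))
        by_intervention[rec.intervention] = (c0 + cases, c1 + controls)
    return CohortSummary(
        n_studies=len({r.study_id for r in records}),
        n_datasets=len(records),
        total_cases=total_cases,
        total_controls=total_controls,
        total_patients=total_cases + total_controls,
        counts_by_quality=by_quality,
        counts_by_intervention=by_intervention,
    )


def hwe_test(n_II: int, n_ID: int, n_DD: int) -> HWEResult:
    """Chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    The D-allele frequency is estimated as ``p = (2*DD + ID) / (2*N)`` and
    genotype counts are compared against expectations ``N*(1-p)^2``,
    ``2*N*p*(1-p)``, ``N*p^2`` on 1 degree of freedom (one parameter, p,
    estimated from three classes).
    """
    total = n_II + n_ID + n_DD
    if total <= 0:
        raise ValueError("hwe_test requires a positive genotype total")
    if min(n_II, n_ID, n_DD) < 0:
        raise ValueError("genotype counts must be non-negative")
    p = (2 * n_DD + n_ID) / (2 * total)
    expected = (total * (1 - p) ** 2, 2 * total * p * (1 - p), total * p ** 2)
    chi2 = 0.0
    for obs, exp in zip((n_II, n_ID, n_DD), expected):
        if exp > 0:
            chi2 += (obs - exp) ** 2 / exp
        # exp == 0 forces obs == 0 (p is estimated from the same counts)
    p_value = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return HWEResult(chi2=float(chi2), df=1, p_value=p_value, allele_freq_D=p)


def bundled_cohort_path() -> Path:
    """Path of the packaged restenosis study-characteristics table."""
    return Path(__file__).parent / "data" / "restenosis_studies.csv"


def load_bundled_cohort() -> list[StudyRecord]:
    """Load the packaged 33-dataset restenosis cohort table."""
    return load_studies(bundled_cohort_path())
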