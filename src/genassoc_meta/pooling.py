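"""Fixed-effect and DerSimonian-Laird random-effects pooling.

The model: study ``i`` yields a log odds ratio ``y_i`` with known sampling
variance ``se_i^2``. Under the random-effects model

    y_i ~ Normal(theta_i, se_i^2),   theta_i ~ Normal(mu, tau^2),

``tau^2`` (between-study variance) is estimated by the DerSimonian-Laird
method of moments from Cochran's Q, and ``mu`` by inverse-variance weighting
with weights ``1/(se_i^2 + tau^2)``. The fixed-effect model is the
``tau^2 = 0`` special case; when Q does not exceed its degrees of freedom
the moment estimate truncates to zero and the two coincide exactly.

Heterogeneity is quantified by Cochran's Q (chi-square test, conventionally
significant at P < 0.10) and the inconsistency index
``I^2 = 100 * max(0, (Q - df) / Q)``, read as the percentage of observed
between-study variability due to heterogeneity rather than chance.

The statsmodels-style entry point is :class:`MetaAnalysis`; its ``fit()``
returns a :class:`PooledResult`. The functional wrappers
(:func:`pool_fixed`, :func:`pool_random_dl`, :func:`cochran_q`,
:func:`i_squared`) expose the individual operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._format import format_het, format_or_ci_p, format_p
from .contrasts import EffectEstimate, GeneticModel, effects_from_records

#: normal quantile used for 95% CIs on the log-OR scale (no small-sample
#: adjustment — matches classical inverse-variance practice)
Z_95 = 1.959964


@dataclass(frozen=True)
class PooledResult:
    """Pooled odds ratio with heterogeneity statistics.

    Returned by :meth:`MetaAnalysis.fit`. All inference is on the log-OR
    scale; ``pooled_or`` and ``ci95`` are the exponentiated summaries.
    """

    k: int
    pooled_log_or: float
    pooled_se: float
    q: float
    p_q: float
    i2: float
    tau2: float
    method: str  # "fixed" | "random"
    weights: dict  # study_id -> normalized weight (sums to 1)
    model: GeneticModel | None = None
    study_ids: tuple = ()

    @property
    def pooled_or(self) -> float:
        return math.exp(self.pooled_log_or)

    @property
    def ci95(self) -> tuple[float, float]:
        half = Z_95 * self.pooled_se
        return (math.exp(self.pooled_log_or - half),
                math.exp(self.pooled_log_or + half))

    @property
    def z(self) -> float:
        return self.pooled_log_or / self.pooled_se

    @property
    def p_z(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))

    def or_ci_p(self) -> str:
        lo, hi = self.ci95
        return format_or_ci_p(self.pooled_or, lo, hi, self.p_z)

    def het_cell(self) -> str:
        return format_het(self.p_q, self.i2)

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "model": self.model.value if self.model is not None else None,
            "method": self.method,
            "k": self.k,
            "pooled_or": self.pooled_or,
            "pooled_log_or": self.pooled_log_or,
            "pooled_se": self.pooled_se,
            "ci95_low": lo,
            "ci95_high": hi,
            "z": self.z,
            "p_z": self.p_z,
            "q": self.q,
            "p_q": self.p_q,
            "i2": self.i2,
            "tau2": self.tau2,
            "weights": dict(self.weights),
        }

    def summary(self) -> str:
        """Plain-text summary table."""
        lo, hi = self.ci95
        name = self.model.value if self.model is not None else "effect"
        lines = [
            f"Meta-analysis ({self.method} effects), {name} contrast",
            "=" * 56,
            f"studies (k)            {self.k:>12d}",
            f"pooled OR              {self.pooled_or:>12.4f}",
            f"95% CI                 {lo:>12.4f} {hi:.4f}",
            f"Z                      {self.z:>12.4f}",
            f"P(Z)                   {format_p(self.p_z):>12s}",
            f"Cochran Q (df={self.k - 1:d})       {self.q:>12.4f}",
            f"P(Q)                   {format_p(self.p_q):>12s}",
            f"I2 (%)                 {self.i2:>12.1f}",
            f"tau2                   {self.tau2:>12.4f}",
            "-" * 56,
            "study weights (normalized):",
        ]
        for sid, w in self.weights.items():
            lines.append(f"  {sid:<30s} {w:>8.4f}")
        return "\n".join(lines)


@dataclass(frozen=True)
class HeterogeneityVerdict:
    significant: bool
    band: str  # none_or_little | moderate | strong


class MetaAnalysis:
    """Inverse-variance meta-analysis model for per-study log odds ratios.

    Parameters
    ----------
    effects : array-like of float
        Per-study log odds ratios.
    se : array-like of float
        Their standard errors (all strictly positive).
    study_ids : sequence of str, optional
        Labels used in weight maps and reports.
    model : GeneticModel, optional
        Genetic contrast the effects were computed under (metadata only).
    """

    def __init__(self, effects, se, study_ids=None, model=None):
        y = np.asarray(effects, dtype=float)
        s = np.asarray(se, dtype=float)
        if y.ndim != 1 or y.shape != s.shape:
            raise ValueError("effects and se must be 1-d arrays of equal length")
        if y.size == 0:
            raise ValueError("at least one study is required")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(s)):
            raise ValueError("effects and se must be finite")
        if np.any(s <= 0):
            raise ValueError("all standard errors must be positive")
        if study_ids is None:
            study_ids = [f"study_{i + 1}" for i in range(y.size)]
        if len(study_ids) != y.size:
            raise ValueError("study_ids length mismatch")
        self.y = y
        self.se = s
        self.study_ids = tuple(str(s_) for s_ in study_ids)
        self.model = GeneticModel(model) if model is not None else None

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_estimates(cls, estimates: Sequence[EffectEstimate]) -> "MetaAnalysis":
        ests = list(estimates)
        if not ests:
            raise ValueError("at least one study is required")
        model = ests[0].model if all(e.model == ests[0].model for e in ests) else None
        return cls([e.log_or for e in ests], [e.se for e in ests],
                   study_ids=[e.study_id for e in ests], model=model)

    @classmethod
    def from_records(cls, records, model: GeneticModel,
                     correction: float = 0.5) -> "MetaAnalysis":
        estimates, _ = effects_from_records(records, model, correction)
        return cls.from_estimates(estimates)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, effect_col: str = "log_or",
                       se_col: str = "se", study_col: str | None = "study_id",
                       model=None) -> "MetaAnalysis":
        ids = df[study_col].tolist() if study_col and study_col in df.columns else None
        return cls(df[effect_col].to_numpy(), df[se_col].to_numpy(),
                   study_ids=ids, model=model)

    # -- fitting ---------------------------------------------------------

    def _fe_weights(self) -> np.ndarray:
        return 1.0 / self.se ** 2

    def heterogeneity(self) -> tuple[float, int, float]:
        """Cochran's Q, its degrees of freedom and chi-square P-value."""
        df = self.y.size - 1
        if df == 0:
            return 0.0, 0, 1.0
        w = self._fe_weights()
        ybar = float(np.sum(w * self.y) / np.sum(w))
        q = float(np.sum(w * (self.y - ybar) ** 2))
        p_q = float(stats.chi2.sf(q, df))
        return q, df, p_q

    def tau2_dl(self) -> float:
        """DerSimonian-Laird moment estimate of between-study variance."""
        if self.y.size == 1:
            return 0.0
        q, df, _ = self.heterogeneity()
        w = self._fe_weights()
        denom = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
        if denom <= 0:
            return 0.0
        return max(0.0, (q - df) / denom)

    def fit(self, method: str = "random") -> PooledResult:
        """Pool the studies.

        ``method="fixed"`` uses inverse-variance weights ``1/se^2``;
        ``method="random"`` (default) adds the DL ``tau^2`` to every study's
        variance. With ``tau^2 = 0`` the two are identical, including the
        reported weights.
        """
        if method not in ("fixed", "random"):
            raise ValueError(f"unknown pooling method {method!r}")
        q, df, p_q = self.heterogeneity()
        i2 = i_squared(q, df)
        tau2 = self.tau2_dl() if method == "random" else 0.0
        w = 1.0 / (self.se ** 2 + tau2)
        sw = float(np.sum(w))
        pooled = float(np.sum(w * self.y) / sw)
        pooled_se = 1.0 / math.sqrt(sw)
        weights = {sid: float(wi / sw) for sid, wi in zip(self.study_ids, w)}
        return PooledResult(
            k=int(self.y.size), pooled_log_or=pooled, pooled_se=pooled_se,
            q=q, p_q=p_q, i2=i2, tau2=tau2, method=method,
            weights=weights, model=self.model, study_ids=self.study_ids,
        )


# ---------------------------------------------------------------------
# functional operations


def cochran_q(estimates: Sequence[EffectEstimate]) -> tuple[float, int, float]:
    """Cochran's heterogeneity Q with fixed-effect weights; (q, df, p_q)."""
    return MetaAnalysis.from_estimates(estimates).heterogeneity()


def i_squared(q: float, df: int) -> float:
    """Inconsistency index ``100 * max(0, (q - df)/q)``; 0 when q = 0."""
    if q < 0 or df < 0:
        raise ValueError("q and df must be non-negative")
    if q == 0:
        return 0.0
    return 100.0 * max(0.0, (q - df) / q)


def pool_fixed(estimates: Sequence[EffectEstimate]) -> PooledResult:
    """Inverse-variance fixed-effect pooling."""
    return MetaAnalysis.from_estimates(estimates).fit(method="fixed")


def pool_random_dl(estimates: Sequence[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effects pooling (single study: tau2 = 0)."""
    return MetaAnalysis.from_estimates(estimates).fit(method="random")


def classify_heterogeneity(result: PooledResult,
                           alpha: float = 0.10) -> HeterogeneityVerdict:
    """Significance (P(Q) < alpha) and the conventional I2 bands.

    I2 below 25% is read as no or little heterogeneity, 25-50% as moderate
    (both boundaries inclusive), above 50% as strong.
    """
    if result.i2 < 25.0:
        band = "none_or_little"
    elif result.i2 <= 50.0:
        band = "moderate"
    else:
        band = "strong"
    return HeterogeneityVerdict(significant=result.p_q < alpha, band=band)
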