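"""Small-study / publication-bias diagnostics.

Funnel-plot coordinates (effect vs precision), the Egger regression
asymmetry test and the Begg-Mazumdar rank-correlation test. In the Egger
test each study's standardized effect ``y_i / se_i`` is regressed on its
precision ``1 / se_i``; under no small-study effect the intercept is zero,
so a two-sided t-test on the intercept (k - 2 df) flags funnel asymmetry.
The classical formulation is unweighted ordinary least squares; a
precision-weighted variant is available behind ``weighted=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .contrasts import EffectEstimate
from .exceptions import InsufficientStudiesError, SingularDesignError
from .pooling import pool_fixed


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    slope: float
    slope_se: float
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class FunnelPoint:
    study_id: str
    effect: float  # log OR
    se: float
    precision: float  # 1 / se


@dataclass(frozen=True)
class BeggResult:
    kendall_tau: float
    p: float


def funnel_data(estimates: Sequence[EffectEstimate]) -> list[FunnelPoint]:
    """One plottable (effect, precision) point per study; inputs untouched."""
    return [FunnelPoint(study_id=e.study_id, effect=e.log_or, se=e.se,
                        precision=1.0 / e.se) for e in estimates]


def funnel_to_tsv(estimates: Sequence[EffectEstimate], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("study_id\tlog_or\tse\tprecision\tstandardized_effect\n")
        for e in estimates:
            fh.write(f"{e.study_id}\t{e.log_or:.6g}\t{e.se:.6g}"
                     f"\t{1.0 / e.se:.6g}\t{e.log_or / e.se:.6g}\n")


def egger_test(estimates: Sequence[EffectEstimate],
               weighted: bool = False) -> EggerResult:
    """Egger regression test for funnel-plot asymmetry.

    OLS of ``y_i/se_i`` on ``1/se_i`` (intercept + slope); the intercept is
    the asymmetry statistic, tested two-sided against Student t with
    ``k - 2`` degrees of freedom. ``weighted=True`` weights the regression
    by ``1/se_i^2``.
    """
    k = len(estimates)
    if k < 3:
        raise InsufficientStudiesError(f"Egger's test needs k >= 3, got {k}")
    se = np.array([e.se for e in estimates], dtype=float)
    y = np.array([e.log_or for e in estimates], dtype=float)
    x = 1.0 / se  # precision
    z = y / se  # standardized effect
    if np.ptp(x) == 0:
        raise SingularDesignError("identical standard errors: Egger design is singular")
    w = x ** 2 if weighted else np.ones_like(x)
    sw = w.sum()
    xbar = float((w * x).sum() / sw)
    zbar = float((w * z).sum() / sw)
    sxx = float((w * (x - xbar) ** 2).sum())
    sxz = float((w * (x - xbar) * (z - zbar)).sum())
    slope = sxz / sxx
    intercept = zbar - slope * xbar
    resid = z - intercept - slope * x
    df = k - 2
    sigma2 = float((w * resid ** 2).sum() / df)
    intercept_se = math.sqrt(sigma2 * (1.0 / sw + xbar ** 2 / sxx))
    slope_se = math.sqrt(sigma2 / sxx)
    t = intercept / intercept_se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return EggerResult(intercept=intercept, intercept_se=intercept_se,
                       slope=slope, slope_se=slope_se, t=t, df=df, p=p)


def begg_test(estimates: Sequence[EffectEstimate]) -> BeggResult:
    """Begg-Mazumdar rank correlation between standardized effects and variances.

    Effects are centered at the fixed-effect pooled estimate and
    standardized by ``sqrt(se_i^2 - se_pooled^2)``; the ties-corrected
    Kendall tau between these and the sampling variances is tested with the
    normal approximation (no continuity correction).
    """
    k = len(estimates)
    if k < 3:
        raise InsufficientStudiesError(f"Begg's test needs k >= 3, got {k}")
    fe = pool_fixed(estimates)
    y = np.array([e.log_or for e in estimates], dtype=float)
    v = np.array([e.se ** 2 for e in estimates], dtype=float)
    vstar = np.maximum(v - fe.pooled_se ** 2, 1e-12)
    t_std = (y - fe.pooled_log_or) / np.sqrt(vstar)
    if np.ptp(v) == 0:
        # variances all tied: no ordering information
        return BeggResult(kendall_tau=0.0, p=1.0)
    tau, p = stats.kendalltau(t_std, v, variant="b", method="asymptotic")
    return BeggResult(kendall_tau=float(tau), p=float(p))
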