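"""Univariate random-effects meta-regression of log odds ratios on moderators.

Model: ``y_i = beta0 + beta1 * x_i + u_i + e_i`` with ``u_i ~ N(0, tau2)``
(residual between-study variance) and ``e_i ~ N(0, se_i^2)``. Weights are
``1/(se_i^2 + tau2)``. ``tau2`` is estimated by the method of moments
(default — the DerSimonian-Laird generalization to regression designs) or
by REML iteration.

One moderator at a time, matching how genetic meta-analyses report
per-covariate heterogeneity explanations; categorical ethnicity is encoded
Asian = 1, Caucasian = 0 (any other group is treated as missing and
dropped with a diagnostic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from ._format import format_p
from .contrasts import EffectEstimate
from .exceptions import InsufficientStudiesError

#: covariate-map encoders; return None for missing
_ENCODERS = {
    "ethnicity": lambda v: {"Asian": 1.0, "Caucasian": 0.0}.get(v),
    "year": lambda v: float(v) if v is not None else None,
    "size": lambda v: float(v) if v is not None else None,
    "followup": lambda v: float(v) if v is not None else None,
    "age": lambda v: float(v) if v is not None else None,
    "pct_male": lambda v: float(v) if v is not None else None,
}


@dataclass(frozen=True)
class MetaRegressionFit:
    """Estimated intercept/slope with residual heterogeneity.

    ``beta1`` (and its ``se1``/``p_beta1``) are ``None`` for a degenerate,
    intercept-only design, in which case ``beta0`` is the random-effects
    pooled log OR.
    """

    moderator: str
    beta0: float
    se0: float
    beta1: float | None
    se1: float | None
    p_beta1: float | None
    tau2_resid: float
    k: int
    method: str
    dropped: tuple = ()

    def summary(self) -> str:
        lines = [
            f"Meta-regression on {self.moderator!r} ({self.method}), k = {self.k}",
            "=" * 56,
            f"intercept  {self.beta0:>10.4f}  (se {self.se0:.4f})",
        ]
        if self.beta1 is not None:
            lines.append(f"slope      {self.beta1:>10.4f}  (se {self.se1:.4f})"
                         f"  P = {format_p(self.p_beta1)}")
        else:
            lines.append("slope      (moderator constant: intercept-only model)")
        lines.append(f"residual tau2 = {self.tau2_resid:.5f}")
        if self.dropped:
            lines.append(f"dropped (missing moderator): {', '.join(self.dropped)}")
        return "\n".join(lines)


class MetaRegression:
    """Weighted meta-regression model for one study-level moderator.

    Parameters
    ----------
    effects, se : array-like
        Per-study log odds ratios and standard errors.
    moderator : array-like
        Moderator value per study (already numerically encoded).
    name : str
        Moderator label carried into the fit.
    """

    def __init__(self, effects, se, moderator, name: str = "x",
                 study_ids=None, dropped=()):
        y = np.asarray(effects, dtype=float)
        s = np.asarray(se, dtype=float)
        x = np.asarray(moderator, dtype=float)
        if not (y.shape == s.shape == x.shape) or y.ndim != 1:
            raise ValueError("effects, se and moderator must be equal-length 1-d")
        if np.any(s <= 0):
            raise ValueError("all standard errors must be positive")
        self.y, self.se, self.x = y, s, x
        self.name = name
        self.dropped = tuple(dropped)

    @property
    def k(self) -> int:
        return self.y.size

    def _design(self) -> np.ndarray:
        if np.ptp(self.x) == 0:  # constant moderator: intercept-only
            return np.ones((self.k, 1))
        return np.column_stack([np.ones(self.k), self.x])

    @staticmethod
    def _wls(X, y, w):
        xtw = X.T * w
        xtwx = xtw @ X
        beta = np.linalg.solve(xtwx, xtw @ y)
        return beta, xtwx

    def _tau2_mm(self, X) -> float:
        """Method-of-moments residual tau2 from the FE-weighted fit."""
        w = 1.0 / self.se ** 2
        beta, xtwx = self._wls(X, self.y, w)
        resid = self.y - X @ beta
        q_e = float(np.sum(w * resid ** 2))
        p = X.shape[1]
        # trace correction: E[Q_E] = (k - p) + tau2 * (tr W - tr[(X'WX)^-1 X'W^2 X])
        xtw2x = (X.T * w ** 2) @ X
        c = float(np.sum(w) - np.trace(np.linalg.solve(xtwx, xtw2x)))
        if c <= 0:
            return 0.0
        return max(0.0, (q_e - (self.k - p)) / c)

    def _tau2_reml(self, X, tol: float = 1e-10) -> float:
        """REML tau2 by 1-d profile-likelihood optimization."""

        def neg_restricted_ll(tau2):
            v = self.se ** 2 + tau2
            w = 1.0 / v
            beta, xtwx = self._wls(X, self.y, w)
            resid = self.y - X @ beta
            sign, logdet = np.linalg.slogdet(xtwx)
            return 0.5 * (np.sum(np.log(v)) + logdet + np.sum(w * resid ** 2))

        hi = max(float(np.var(self.y)) * 10.0 + 1.0, 10.0 * self._tau2_mm(X) + 1.0)
        res = optimize.minimize_scalar(neg_restricted_ll, bounds=(0.0, hi),
                                       method="bounded",
                                       options={"xatol": tol})
        return max(0.0, float(res.x))

    def fit(self, method: str = "mm") -> MetaRegressionFit:
        """Estimate tau2 (``mm`` or ``reml``), then weighted LS for the betas.

        Slope P-values are two-sided normal (large-sample Wald), the
        convention of the moment-based meta-regression literature.
        """
        if method not in ("mm", "reml"):
            raise ValueError(f"unknown tau2 method {method!r}")
        X = self._design()
        slope_fit = X.shape[1] == 2
        if slope_fit and self.k < 3:
            raise InsufficientStudiesError(
                f"meta-regression slope fit needs k >= 3, got {self.k}")
        tau2 = self._tau2_mm(X) if method == "mm" else self._tau2_reml(X)
        w = 1.0 / (self.se ** 2 + tau2)
        beta, xtwx = self._wls(X, self.y, w)
        cov = np.linalg.inv(xtwx)
        se = np.sqrt(np.diag(cov))
        if slope_fit:
            z = beta[1] / se[1]
            p1 = float(2.0 * stats.norm.sf(abs(z)))
            return MetaRegressionFit(self.name, float(beta[0]), float(se[0]),
                                     float(beta[1]), float(se[1]), p1,
                                     float(tau2), self.k, method, self.dropped)
        return MetaRegressionFit(self.name, float(beta[0]), float(se[0]),
                                 None, None, None, float(tau2), self.k,
                                 method, self.dropped)


def encode_moderator(estimate: EffectEstimate, moderator: str):
    """Numeric moderator value from an estimate's covariate map (None if missing)."""
    encoder = _ENCODERS.get(moderator)
    raw = estimate.covariates.get(moderator)
    if encoder is None:
        return float(raw) if raw is not None else None
    return encoder(raw)


def meta_regress(estimates: Sequence[EffectEstimate], moderator: str,
                 method: str = "mm") -> MetaRegressionFit:
    """Univariate meta-regression of study effects on one named moderator.

    Studies with a missing moderator are dropped (ids recorded on the fit);
    fewer than 3 usable studies raises :class:`InsufficientStudiesError`.
    """
    kept, xs, dropped = [], [], []
    for e in estimates:
        x = encode_moderator(e, moderator)
        if x is None:
            dropped.append(e.study_id)
        else:
            kept.append(e)
            xs.append(x)
    if len(kept) < 3:
        raise InsufficientStudiesError(
            f"meta-regression on {moderator!r}: only {len(kept)} studies "
            "with a non-missing moderator (need >= 3)")
    model = MetaRegression([e.log_or for e in kept], [e.se for e in kept],
                           xs, name=moderator,
                           study_ids=[e.study_id for e in kept],
                           dropped=dropped)
    return model.fit(method=method)


def metareg_to_tsv(fits: Sequence[MetaRegressionFit], path) -> None:
    """Results table: moderator, beta1, se1, p, tau2_resid, k."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("moderator\tbeta1\tse1\tp\ttau2_resid\tk\n")
        for f in fits:
            if f.beta1 is None:
                fh.write(f"{f.moderator}\tNA\tNA\tNA\t{f.tau2_resid:.6g}\t{f.k}\n")
            else:
                fh.write(f"{f.moderator}\t{f.beta1:.6g}\t{f.se1:.6g}"
                         f"\t{f.p_beta1:.6g}\t{f.tau2_resid:.6g}\t{f.k}\n")
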