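"""Report formatting conventions shared by results objects and reports."""

from __future__ import annotations

import math


def format_p(p: float) -> str:
    """P-value to 3 significant figures; '<10^-4' below 1e-4."""
    if p < 1e-4:
        return "<10^-4"
    return f"{p:.3g}"


def format_or_ci(or_: float, lo: float, hi: float) -> str:
    return f"{or_:.2f} ({lo:.2f}-{hi:.2f})"


def format_or_ci_p(or_: float, lo: float, hi: float, p: float) -> str:
    """The 'OR (low-high); P' cell format used in pooled-result tables."""
    return f"{format_or_ci(or_, lo, hi)}; {format_p(p)}"


def format_het(p_q: float, i2: float) -> str:
    """The 'P(Q); I2' heterogeneity cell format."""
    i2r = int(round(i2))
    return f"{format_p(p_q)}; {i2r}%"
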