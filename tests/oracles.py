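"""Independent oracle implementations used only by the test suite.

Each oracle is deliberately coded from the textbook definitions with plain
loops, independent of the package's vectorized implementations, so that
agreement between the two routes is meaningful.
"""

import math


def fixed_pool_oracle(y, v):
    """Inverse-variance fixed-effect mean and variance; plain-loop textbook form."""
    sw = swy = 0.0
    for yi, vi in zip(y, v):
        w = 1.0 / vi
        sw += w
        swy += w * yi
    return swy / sw, 1.0 / sw


def cochran_q_oracle(y, v):
    mu, _ = fixed_pool_oracle(y, v)
    q = 0.0
    for yi, vi in zip(y, v):
        q += (yi - mu) ** 2 / vi
    return q


def dl_oracle(y, v):
    """DerSimonian-Laird pooled mean, variance and tau2, textbook formulas."""
    k = len(y)
    q = cochran_q_oracle(y, v)
    sw = sum(1.0 / vi for vi in v)
    sw2 = sum((1.0 / vi) ** 2 for vi in v)
    denom = sw - sw2 / sw
    tau2 = max(0.0, (q - (k - 1)) / denom) if k > 1 and denom > 0 else 0.0
    swr = swy = 0.0
    for yi, vi in zip(y, v):
        w = 1.0 / (vi + tau2)
        swr += w
        swy += w * yi
    return swy / swr, 1.0 / swr, tau2


def i2_oracle(q, df):
    if q <= 0:
        return 0.0
    return max(0.0, (q - df) / q) * 100.0


def egger_oracle(y, se):
    """Egger regression via statsmodels OLS on the standardized pairs."""
    import numpy as np
    import statsmodels.api as sm

    z = np.asarray(y) / np.asarray(se)
    x = sm.add_constant(1.0 / np.asarray(se))
    fit = sm.OLS(z, x).fit()
    return (fit.params[0], fit.bse[0], fit.params[1], fit.pvalues[0])


def kendall_tau_b_oracle(x, y):
    """Ties-corrected Kendall tau by exhaustive pair enumeration."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    if denom == 0:
        return 0.0
    return (concordant - discordant) / denom
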