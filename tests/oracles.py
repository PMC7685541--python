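"""Closed-form power oracles used by the test suite.

These are independent of the package implementation: they evaluate
textbook formulas through scipy distribution functions only.
"""

import numpy as np
from scipy import stats


def fixed_design_regression_power(r, n, alpha=0.05):
    """Noncentral-t power of a simple-regression slope test when the
    predictor column is standardized in-sample (sum of squares = n),
    which is exactly the outcome-construction scheme of the regression
    power module: ncp = r*sqrt(n)/sqrt(1-r^2)."""
    df = n - 2
    ncp = r * np.sqrt(n) / np.sqrt(1.0 - r * r)
    tc = stats.t.ppf(1 - alpha / 2, df)
    return stats.nct.sf(tc, df, ncp) + stats.nct.cdf(-tc, df, ncp)


def fisher_z_power(r, n, alpha=0.05):
    """Fisher z approximation to the power of the test of zero Pearson
    correlation."""
    za = stats.norm.ppf(1 - alpha / 2)
    lam = np.arctanh(r) * np.sqrt(n - 3)
    return stats.norm.sf(za - lam) + stats.norm.cdf(-za - lam)


def two_sample_t_power(d, n, alpha=0.05):
    """Power of the two-sided two-sample t test at Cohen's d with n per
    group (equivalent to one-way ANOVA with two groups)."""
    df = 2 * n - 2
    ncp = d * np.sqrt(n / 2.0)
    tc = stats.t.ppf(1 - alpha / 2, df)
    return stats.nct.sf(tc, df, ncp) + stats.nct.cdf(-tc, df, ncp)
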