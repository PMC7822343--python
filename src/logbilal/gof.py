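"""Goodness-of-fit battery for fitted unit-interval distributions.

Given a sample and a fitted cdf, reports the Kolmogorov-Smirnov statistic
with its asymptotic p-value, the Cramér-von Mises W² and Anderson-Darling A²
statistics computed from the probability-integral transforms, and the
AIC/BIC model-selection criteria — the usual table for ranking competing
one- and two-parameter families on the same data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import special

from .distribution import as_unit_values

__all__ = ["GofReport", "gof_report"]


@dataclass
class GofReport:
    ks_stat: float
    ks_pvalue: float
    cvm_stat: float  # W^2
    ad_stat: float  # A^2
    aic: float
    bic: float
    loglik: float
    n_params: int
    n_obs: int


def gof_report(
    sample, fitted_cdf: Callable, n_params: int, loglik: float
) -> GofReport:
    """Compute the full battery at the fitted parameters.

    The classical (unmodified) statistics are used throughout:

    - K-S: D = max(max_i(i/n - u_(i)), max_i(u_(i) - (i-1)/n)), p-value from
      the asymptotic Kolmogorov distribution of sqrt(n) D.
    - W² = sum_i (u_(i) - (2i-1)/(2n))² + 1/(12n)
    - A² = -n - (1/n) sum_i (2i-1) [ln u_(i) + ln(1 - u_(n+1-i))]

    with u_(i) the sorted probability-integral transforms F(y_(i)).  No
    parameter-uncertainty correction is applied: the statistics describe the
    fitted cdf as given, matching standard fitted-distribution practice.
    """
    y = as_unit_values(sample)
    n = y.size
    u = np.sort(np.asarray(fitted_cdf(np.sort(y)), dtype=float), kind="stable")
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        warnings.warn(
            "probability-integral transforms at 0 or 1 clipped (A² would be infinite)",
            RuntimeWarning,
            stacklevel=2,
        )
        u = np.clip(u, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    i = np.arange(1, n + 1, dtype=float)

    d_plus = np.max(i / n - u)
    d_minus = np.max(u - (i - 1.0) / n)
    ks = max(d_plus, d_minus)
    ks_p = float(special.kolmogorov(np.sqrt(n) * ks))

    w2 = float(np.sum((u - (2.0 * i - 1.0) / (2.0 * n)) ** 2) + 1.0 / (12.0 * n))
    a2 = float(-n - np.mean((2.0 * i - 1.0) * (np.log(u) + np.log1p(-u[::-1]))))

    return GofReport(
        ks_stat=float(ks),
        ks_pvalue=ks_p,
        cvm_stat=w2,
        ad_stat=a2,
        aic=-2.0 * loglik + 2.0 * n_params,
        bic=-2.0 * loglik + n_params * np.log(n),
        loglik=float(loglik),
        n_params=int(n_params),
        n_obs=n,
    )
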