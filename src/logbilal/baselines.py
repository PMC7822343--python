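"""Competitor unit-interval families: beta, Kumaraswamy, Topp-Leone,
unit-Lindley.

These are the standard comparison set for a new distribution on (0,1).
Each family exposes pdf/logpdf/cdf plus a maximum-likelihood fit with
standard errors from the observed information, so a model-comparison table
(estimates, AIC/BIC, GOF statistics) runs end-to-end in one package.

The beta density is delegated to scipy; the Kumaraswamy, Topp-Leone and
unit-Lindley densities are implemented from their closed forms:

    Kumaraswamy:  f = a b y^(a-1) (1 - y^a)^(b-1),        F = 1 - (1-y^a)^b
    Topp-Leone:   f = t (2 - 2y) (2y - y^2)^(t-1),        F = (2y - y^2)^t
    unit-Lindley: f = t^2/(1+t) (1-y)^{-3} e^{-t y/(1-y)},
                  F = 1 - (1 + t y/((1+t)(1-y))) e^{-t y/(1-y)}

(unit-Lindley is the law of X/(1+X) for X Lindley-distributed.)
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats
from statsmodels.tools import numdiff

from .distribution import as_unit_values
from .estimation import EstimateResult

__all__ = [
    "FAMILIES",
    "baseline_pdf",
    "baseline_logpdf",
    "baseline_cdf",
    "fit_baseline",
]

FAMILIES = ("beta", "kumaraswamy", "topp_leone", "unit_lindley")
_N_PARAMS = {"beta": 2, "kumaraswamy": 2, "topp_leone": 1, "unit_lindley": 1}


def _check(family: str, params) -> np.ndarray:
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose one of {FAMILIES}")
    p = np.asarray(params, dtype=float).ravel()
    if p.size != _N_PARAMS[family]:
        raise ValueError(f"{family} takes {_N_PARAMS[family]} parameter(s), got {p.size}")
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0):
        raise ValueError(f"{family} parameters must be positive, got {p}")
    return p


def baseline_logpdf(family: str, params, y):
    p = _check(family, params)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ValueError("y must lie strictly inside (0, 1)")
    ly = np.log(y)
    l1y = np.log1p(-y)
    if family == "beta":
        return stats.beta.logpdf(y, p[0], p[1])
    if family == "kumaraswamy":
        a, b = p
        return np.log(a * b) + (a - 1.0) * ly + (b - 1.0) * np.log1p(-np.exp(a * ly))
    if family == "topp_leone":
        t = p[0]
        return np.log(t) + np.log(2.0) + l1y + (t - 1.0) * np.log(y * (2.0 - y))
    t = p[0]  # unit_lindley
    return 2.0 * np.log(t) - np.log1p(t) - 3.0 * l1y - t * y / (1.0 - y)


def baseline_pdf(family: str, params, y):
    return np.exp(baseline_logpdf(family, params, y))


def baseline_cdf(family: str, params, y):
    p = _check(family, params)
    y = np.asarray(y, dtype=float)
    if np.any(y < 0.0) or np.any(y > 1.0):
        raise ValueError("y must lie in [0, 1]")
    if family == "beta":
        return stats.beta.cdf(y, p[0], p[1])
    if family == "kumaraswamy":
        a, b = p
        return 1.0 - (1.0 - y**a) ** b
    if family == "topp_leone":
        return (y * (2.0 - y)) ** p[0]
    t = p[0]
    with np.errstate(divide="ignore"):
        z = np.where(y < 1.0, t * y / (1.0 - y), np.inf)
    return 1.0 - (1.0 + z / (1.0 + t)) * np.exp(-z)


def _start(family: str, y: np.ndarray) -> np.ndarray:
    m, v = float(np.mean(y)), float(np.var(y))
    if family in ("beta", "kumaraswamy"):
        # beta method-of-moments start; reasonable for Kumaraswamy too
        c = m * (1.0 - m) / max(v, 1e-12) - 1.0
        c = max(c, 1e-2)
        return np.array([max(m * c, 1e-2), max((1.0 - m) * c, 1e-2)])
    if family == "topp_leone":
        return np.array([1.0])
    x = y / (1.0 - y)  # unit-Lindley: underlying Lindley variable
    return np.array([max(1.0 / max(np.mean(x), 1e-12), 1e-3)])


def fit_baseline(family: str, sample) -> EstimateResult:
    """MLE for a baseline family, with SEs from the numerical Hessian.

    Two-parameter families are optimized quasi-Newton in log-parameter space
    from moment-based starts; the one-parameter families have unimodal
    likelihoods and are solved by bounded scalar optimization.
    """
    y = as_unit_values(sample)
    k = _N_PARAMS[family]
    if y.size < k + 1:
        raise ValueError(f"need at least {k + 1} observations to fit {family}")

    def negll_params(p):
        return -float(np.sum(baseline_logpdf(family, p, y)))

    if k == 1:
        res = optimize.minimize_scalar(
            lambda lt: negll_params([np.exp(lt)]),
            bounds=(np.log(1e-6), np.log(1e6)),
            method="bounded",
            options={"xatol": 1e-12},
        )
        params = np.array([np.exp(res.x)])
        converged = bool(res.success)
    else:
        res = optimize.minimize(
            lambda lp: negll_params(np.exp(lp)),
            np.log(_start(family, y)),
            method="BFGS",
            options={"gtol": 1e-9},
        )
        if not res.success:
            res = optimize.minimize(
                lambda lp: negll_params(np.exp(lp)),
                res.x,
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12},
            )
        params = np.exp(res.x)
        converged = bool(res.success)

    hess = numdiff.approx_hess(params, negll_params)
    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(hess)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            se = np.full(k, np.nan)
    ll = -negll_params(params)
    return EstimateResult(
        method="MLE",
        theta_hat=float(params[0]) if k == 1 else float("nan"),
        n_obs=y.size,
        converged=converged,
        std_error=float(se[0]) if k == 1 else None,
        loglik=ll,
        extra={"family": family, "params": params, "std_errors": se},
    )
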