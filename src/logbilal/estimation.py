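"""Point estimators of the log-Bilal shape parameter.

Four classical routes are provided: maximum likelihood (numerical, with an
observed-information standard error), method of moments (closed form),
and (weighted) least squares on the distribution function evaluated at the
order statistics against the plotting positions i/(n+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .distribution import (
    as_unit_values,
    cdf,
    logpdf,
    mu_from_theta,
    theta_from_mu,
)

__all__ = [
    "EstimateResult",
    "loglik",
    "score",
    "fit_mle",
    "fit_mm",
    "fit_ls",
    "wlse_weights",
]


@dataclass
class EstimateResult:
    """Outcome of a one-parameter fit.

    ``std_error`` and ``loglik`` are populated for the MLE only;
    ``objective`` holds the minimized criterion for the LS/WLS routes.
    """

    method: str
    theta_hat: float
    n_obs: int
    converged: bool
    std_error: float | None = None
    loglik: float | None = None
    objective: float | None = None
    message: str = ""
    extra: dict = field(default_factory=dict)


def loglik(theta, sample) -> float:
    """Log-likelihood l(theta) = n ln(6/theta) + (2/theta - 1) sum ln y_i
    + sum ln(1 - y_i^(1/theta)).

    The data enter only through sums of ln y_i (the sufficient statistic)
    and the power transforms y_i^(1/theta); equivalently this is
    sum_i log f(y_i; theta).
    """
    y = as_unit_values(sample)
    return float(np.sum(logpdf(y, theta)))


def score(theta, sample) -> float:
    """d l / d theta.

    -n/theta - (2/theta^2) sum ln y_i
    + (1/theta^2) sum y_i^(1/theta) ln y_i / (1 - y_i^(1/theta)).
    The second term uses the mean of ln y_i, not of y_i: only that reading
    is the derivative of sum log f (the y_i-mean appears in the method of
    moments, where it genuinely is the arithmetic mean).
    """
    y = as_unit_values(sample)
    theta = float(theta)
    n = y.size
    ly = np.log(y)
    p = np.exp(ly / theta)  # y^(1/theta)
    return float(-n / theta - 2.0 * np.sum(ly) / theta**2 + np.sum(p * ly / (1.0 - p)) / theta**2)


def fit_mm(sample) -> EstimateResult:
    """Method of moments: equate E(Y) = 6/((theta+2)(theta+3)) to the sample
    mean of the y_i, giving theta_hat = ((ybar/(ybar+24))^(-1/2) - 5)/2."""
    y = as_unit_values(sample)
    ybar = float(np.mean(y))
    theta_hat = float(theta_from_mu(ybar))
    if theta_hat <= 0.0:
        raise ValueError(
            f"sample mean {ybar:.6g} >= 1/2 maps to a non-positive shape estimate; "
            "the moment equation has no admissible root"
        )
    return EstimateResult(method="MM", theta_hat=theta_hat, n_obs=y.size, converged=True)


def _observed_information_se(theta_hat: float, y: np.ndarray) -> float:
    """SE from the negative inverse second derivative of the log-likelihood,
    by central differencing of the analytic score at theta_hat."""
    h = 1e-5 * max(1.0, theta_hat)
    d2 = (score(theta_hat + h, y) - score(theta_hat - h, y)) / (2.0 * h)
    if d2 >= 0.0:
        return float("nan")
    return float(1.0 / np.sqrt(-d2))


def fit_mle(sample) -> EstimateResult:
    """Maximum likelihood by direct maximization of the log-likelihood.

    The optimization runs over log(theta) (unconstrained) starting from the
    moment estimate; the standard error comes from the observed information
    at the optimum.
    """
    y = as_unit_values(sample)
    if y.size < 2:
        raise ValueError("MLE needs at least two observations")
    try:
        start = np.log(fit_mm(y).theta_hat)
    except ValueError:
        start = 0.0
    res = optimize.minimize(
        lambda lt: -loglik(np.exp(lt[0]), y),
        x0=[start],
        jac=lambda lt: [-score(np.exp(lt[0]), y) * np.exp(lt[0])],
        method="BFGS",
        options={"gtol": 1e-10},
    )
    theta_hat = float(np.exp(res.x[0]))
    sc = score(theta_hat, y)
    converged = bool(res.success or abs(sc) < 1e-6 * max(1.0, y.size))
    return EstimateResult(
        method="MLE",
        theta_hat=theta_hat,
        n_obs=y.size,
        converged=converged,
        std_error=_observed_information_se(theta_hat, y),
        loglik=loglik(theta_hat, y),
        message=res.message,
        extra={"score_at_opt": sc, "n_iter": int(res.nit)},
    )


def wlse_weights(n: int) -> np.ndarray:
    """Weights (n+1)^2 (n+2) / (i (n - i + 1)) for order statistics i=1..n
    (inverse variances of the uniform order statistics, up to scale)."""
    i = np.arange(1, n + 1, dtype=float)
    return (n + 1.0) ** 2 * (n + 2.0) / (i * (n - i + 1.0))


def _ls_objective(theta, y_sorted: np.ndarray, weights: np.ndarray) -> float:
    n = y_sorted.size
    p = np.arange(1, n + 1, dtype=float) / (n + 1.0)
    resid = cdf(y_sorted, theta) - p
    return float(np.sum(weights * resid**2))


def fit_ls(sample, weighted: bool = False) -> EstimateResult:
    """(Weighted) least squares on the cdf at the order statistics.

    Minimizes sum_i w_i [F(y_(i); theta) - i/(n+1)]^2 over log(theta);
    w_i = 1 for LSE and the inverse-variance weights for WLSE.  Ties are
    ordered by a stable sort, so equal observations keep their input order.
    """
    y = as_unit_values(sample)
    if y.size < 2:
        raise ValueError("least-squares fitting needs at least two observations")
    y_sorted = np.sort(y, kind="stable")
    w = wlse_weights(y.size) if weighted else np.ones(y.size)
    res = optimize.minimize_scalar(
        lambda lt: _ls_objective(np.exp(lt), y_sorted, w),
        bounds=(np.log(1e-4), np.log(1e4)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return EstimateResult(
        method="WLSE" if weighted else "LSE",
        theta_hat=float(np.exp(res.x)),
        n_obs=y.size,
        converged=bool(res.success if res.success is not None else True),
        objective=float(res.fun),
    )
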