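"""Mean-parametrized log-Bilal regression for bounded responses.

The distribution mean ``mu = 6/((theta+2)(theta+3))`` is linked to covariates
through a logit link, ``mu_i = expit(x_i' beta)``, so the model describes
E(Y | x) directly — the same device that makes beta regression and the
unit-Lindley regression usable for proportions.  The likelihood is the
product of log-Bilal densities with per-observation shape
``theta_i = theta(mu_i)``; coefficients are estimated by quasi-Newton
maximization, standard errors come from the observed information matrix
(numerical Hessian), and model adequacy is checked with quantile residuals,
which are standard normal under a correctly specified model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

from .distribution import cdf, logpdf, theta_from_mu

__all__ = [
    "RegressionDesign",
    "RegressionFit",
    "reg_loglik",
    "fit_regression",
    "quantile_residuals",
]

_ETA_MAX = 35.0  # |linear predictor| cap; expit(35) is 1 - 6e-16


class RankDeficientError(np.linalg.LinAlgError):
    """Covariate matrix does not have full column rank."""


class HessianError(np.linalg.LinAlgError):
    """Observed information at the optimum is not positive definite."""


class ConvergenceError(RuntimeError):
    """The optimizer failed to locate a maximum of the likelihood."""


@dataclass(frozen=True)
class RegressionDesign:
    """Response in (0,1) plus covariate matrix with a leading intercept column."""

    response: np.ndarray
    covariates: np.ndarray
    covariate_names: tuple[str, ...]

    def __init__(self, response, covariates, covariate_names=None) -> None:
        y = np.asarray(response, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if np.any(~np.isfinite(y)) or np.any(y <= 0.0) or np.any(y >= 1.0):
            raise ValueError("response values must lie strictly inside (0, 1)")
        if X.shape[0] != y.size:
            raise ValueError(
                f"covariate matrix has {X.shape[0]} rows but the response has {y.size}"
            )
        if not np.all(X[:, 0] == 1.0):
            raise ValueError("the first covariate column must be the intercept (all ones)")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise RankDeficientError(
                f"covariate matrix is rank deficient (rank < {X.shape[1]} columns)"
            )
        if covariate_names is None:
            covariate_names = ["intercept"] + [f"x{j}" for j in range(1, X.shape[1])]
        if len(covariate_names) != X.shape[1]:
            raise ValueError("covariate_names length must match the number of columns")
        object.__setattr__(self, "response", y)
        object.__setattr__(self, "covariates", X)
        object.__setattr__(self, "covariate_names", tuple(covariate_names))

    @property
    def n(self) -> int:
        return int(self.response.size)

    @property
    def p(self) -> int:
        return int(self.covariates.shape[1])

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, response: str, covariates: list[str]
    ) -> "RegressionDesign":
        """Build a design from a DataFrame, prepending the intercept."""
        y = frame[response].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(frame))] + [frame[c].to_numpy(dtype=float) for c in covariates]
        )
        return cls(y, X, ["intercept"] + list(covariates))


@dataclass
class RegressionFit:
    beta: np.ndarray
    std_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    loglik: float
    aic: float
    bic: float
    fitted_mu: np.ndarray
    residuals: np.ndarray
    converged: bool
    covariate_names: tuple[str, ...]
    n_obs: int
    extra: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "std_error": self.std_errors,
                "z": self.z_values,
                "p_value": self.p_values,
            },
            index=list(self.covariate_names),
        )


def _mu_of_eta(eta: np.ndarray) -> np.ndarray:
    return special.expit(np.clip(eta, -_ETA_MAX, _ETA_MAX))


def reg_loglik(beta, design: RegressionDesign) -> float:
    """Log-likelihood of the regression model at coefficient vector beta.

    Evaluated as sum_i log f(y_i; theta(mu_i)) with mu_i = expit(x_i' beta);
    algebraically identical to expanding the mean-parametrized density, but
    numerically safe for extreme linear predictors.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.size != design.p:
        raise ValueError(f"beta has {beta.size} entries, design has {design.p} columns")
    if np.any(~np.isfinite(beta)):
        return -np.inf
    mu = _mu_of_eta(design.covariates @ beta)
    theta = theta_from_mu(mu)
    return float(np.sum(logpdf(design.response, theta)))


def _default_start(design: RegressionDesign) -> np.ndarray:
    beta0 = np.zeros(design.p)
    beta0[0] = special.logit(float(np.mean(design.response)))
    return beta0


def fit_regression(
    design: RegressionDesign, start=None, maxiter: int = 500
) -> RegressionFit:
    """Fit the log-Bilal regression by maximum likelihood.

    Quasi-Newton (BFGS) on the negative log-likelihood with finite-difference
    gradients; the default start puts the intercept at logit(mean(y)) and all
    slopes at zero.  Standard errors are the square roots of the diagonal of
    the inverse observed information (numerical Hessian of -loglik at the
    optimum); Wald z statistics are referred to the standard normal.
    """
    if design.n <= design.p:
        raise ValueError("need more observations than coefficients")
    x0 = _default_start(design) if start is None else np.asarray(start, dtype=float)

    def negll(b):
        return -reg_loglik(b, design)

    res = optimize.minimize(negll, x0, method="BFGS", options={"gtol": 1e-8, "maxiter": maxiter})
    if not res.success:
        # BFGS can stall on precision loss while already at the optimum;
        # polish with Nelder-Mead and accept if the gradient is tiny.
        res2 = optimize.minimize(
            negll, res.x, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12}
        )
        if res2.fun <= res.fun:
            res = res2
    grad = numdiff.approx_fprime(res.x, negll, centered=True)
    converged = bool(res.success or np.max(np.abs(grad)) < 1e-4)
    if not converged:
        raise ConvergenceError(
            f"likelihood maximization did not converge: {res.message} "
            f"(max |gradient| = {np.max(np.abs(grad)):.3g})"
        )
    beta_hat = res.x
    hess = numdiff.approx_hess(beta_hat, negll)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as err:
        raise HessianError("observed information matrix is singular") from err
    diag = np.diag(cov)
    if np.any(diag <= 0.0):
        raise HessianError(
            "observed information is not positive definite at the optimum"
        )
    se = np.sqrt(diag)
    z = beta_hat / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    ll = float(-res.fun)
    p = design.p
    fit = RegressionFit(
        beta=beta_hat,
        std_errors=se,
        z_values=z,
        p_values=pvals,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * p,
        bic=-2.0 * ll + p * np.log(design.n),
        fitted_mu=_mu_of_eta(design.covariates @ beta_hat),
        residuals=np.empty(0),
        converged=converged,
        covariate_names=design.covariate_names,
        n_obs=design.n,
        extra={"n_iter": int(res.nit), "message": res.message},
    )
    fit.residuals = quantile_residuals(fit, design)
    return fit


def quantile_residuals(fit: RegressionFit, design: RegressionDesign) -> np.ndarray:
    """Quantile residuals r_i = Phi^{-1}(F(y_i; theta(mu_hat_i))).

    The response is continuous, so no randomization is needed: the
    probability-integral transform u_i is deterministic.  Under a correctly
    specified model the r_i are i.i.d. standard normal.
    """
    theta = theta_from_mu(fit.fitted_mu)
    u = cdf(design.response, theta)
    eps = np.finfo(float).tiny
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        warnings.warn(
            "probability-integral transforms at 0 or 1 were clipped before "
            "the normal quantile transform",
            RuntimeWarning,
            stacklevel=2,
        )
        u = np.clip(u, eps, 1.0 - np.finfo(float).epsneg)
    return stats.norm.ppf(u)
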