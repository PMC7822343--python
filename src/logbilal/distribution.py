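"""Closed-form functions of the log-Bilal distribution.

The log-Bilal law is the distribution of ``Y = exp(-X)`` where ``X`` follows
the Bilal lifetime distribution.  It has support on the open unit interval
and a single shape parameter ``theta > 0``:

    pdf   f(y; theta) = (6/theta) * y**(2/theta - 1) * (1 - y**(1/theta))
    cdf   F(y; theta) = 3*y**(2/theta) - 2*y**(3/theta)

Small ``theta`` concentrates mass near 1, large ``theta`` near 0; at
``theta = 1`` the density reduces to the Beta(2, 2) density ``6*y*(1-y)``.
All moments are rational in ``theta``, which is what makes the mean
reparametrization (:func:`theta_from_mu` / :func:`mu_from_theta`) exact and
the distribution convenient for bounded-response regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "UnitSample",
    "pdf",
    "logpdf",
    "cdf",
    "sf",
    "hrf",
    "quantile",
    "sample",
    "raw_moment",
    "mean",
    "variance",
    "incomplete_moment",
    "theta_from_mu",
    "mu_from_theta",
    "expfam_components",
    "hrf_shape_diagnostic",
]


def _check_theta(theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if np.any(~np.isfinite(theta)) or np.any(theta <= 0.0):
        raise ValueError(f"shape parameter theta must be a positive finite real, got {theta}")
    return theta


def _check_open_unit(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0.0) or np.any(x >= 1.0):
        raise ValueError(f"{name} must lie strictly inside (0, 1)")
    return x


def _pow(y: np.ndarray, a) -> np.ndarray:
    # y**a via exp(a*log y); y is interior so log is finite, and the result
    # underflows gracefully to 0 instead of overflowing for extreme a.
    return np.exp(np.multiply(a, np.log(y)))


@dataclass(frozen=True)
class UnitSample:
    """A sample of values strictly inside (0, 1).

    Values equal to 0 or 1 are rejected at construction, never clamped:
    the density is only defined on the open interval and a silent clamp
    would bias every estimator downstream.
    """

    values: np.ndarray

    def __init__(self, values) -> None:
        arr = np.atleast_1d(np.asarray(values, dtype=float)).ravel()
        if arr.size < 1:
            raise ValueError("a UnitSample needs at least one observation")
        bad = ~np.isfinite(arr) | (arr <= 0.0) | (arr >= 1.0)
        if np.any(bad):
            idx = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"observation {idx} (value {arr[idx]!r}) is outside the open interval (0, 1); "
                "boundary values are rejected, not clamped"
            )
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n


def as_unit_values(sample) -> np.ndarray:
    """Coerce a UnitSample or array-like to a validated float array."""
    if isinstance(sample, UnitSample):
        return sample.values
    return UnitSample(sample).values


def pdf(y, theta):
    """Density f(y; theta) = (6/theta) y^(2/theta - 1) (1 - y^(1/theta))."""
    theta = _check_theta(theta)
    y = _check_open_unit(y, "y")
    return (6.0 / theta) * _pow(y, 2.0 / theta - 1.0) * (1.0 - _pow(y, 1.0 / theta))


def logpdf(y, theta):
    """log f, evaluated directly for numerical range (used by likelihoods)."""
    theta = _check_theta(theta)
    y = _check_open_unit(y, "y")
    ly = np.log(y)
    return np.log(6.0 / theta) + (2.0 / theta - 1.0) * ly + np.log1p(-np.exp(ly / theta))


def cdf(y, theta):
    """F(y; theta) = 3 y^(2/theta) - 2 y^(3/theta), with F(0)=0, F(1)=1."""
    theta = _check_theta(theta)
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)) or np.any(y < 0.0) or np.any(y > 1.0):
        raise ValueError("y must lie in the closed interval [0, 1] for the cdf")
    yb, tb = np.broadcast_arrays(y, theta)
    yb = np.atleast_1d(yb)
    tb = np.atleast_1d(tb)
    out = np.where(yb == 1.0, 1.0, 0.0)
    interior = (yb > 0.0) & (yb < 1.0)
    yi, ti = yb[interior], tb[interior]
    out[interior] = 3.0 * _pow(yi, 2.0 / ti) - 2.0 * _pow(yi, 3.0 / ti)
    if np.ndim(y) == 0 and np.ndim(theta) == 0:
        return float(out[0])
    return out


def sf(y, theta):
    """Survival function 1 - F(y; theta)."""
    return 1.0 - cdf(y, theta)


def hrf(y, theta):
    """Hazard rate f/(1-F); increasing or bathtub-shaped depending on theta."""
    return pdf(y, theta) / sf(y, theta)


def quantile(u, theta):
    """Inverse cdf.

    The cubic ``3t**2 - 2t**3 = u`` has the unique root in [0, 1]
    ``t = 1/2 - sin(arcsin(1 - 2u)/3)`` (the printed Cardano radicals are
    complex-valued on (0, 1); the trigonometric form is the stable real
    equivalent).  Then ``Q(u) = t**theta``.
    """
    theta = _check_theta(theta)
    u = np.asarray(u, dtype=float)
    if np.any(~np.isfinite(u)) or np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("u must lie strictly inside (0, 1)")
    t = 0.5 - np.sin(np.arcsin(1.0 - 2.0 * u) / 3.0)
    return _pow(t, theta)


def sample(n: int, theta, seed=None, rng: np.random.Generator | None = None) -> UnitSample:
    """Draw n i.i.d. variates by inverse-transform of uniforms.

    Reproducibility is defined by the uniform stream: a fixed seed yields
    the same uniforms, hence the same variates, for any theta.
    """
    _check_theta(theta)
    if n < 1:
        raise ValueError("n must be a positive integer")
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.uniform(size=int(n))
    # uniform() can return exactly 0.0; the open-interval quantile rejects it
    u = np.where(u == 0.0, np.nextafter(0.0, 1.0), u)
    return UnitSample(quantile(u, theta))


def raw_moment(k: int, theta):
    """E(Y^k) = 6 / ((k*theta + 2)(k*theta + 3))."""
    theta = _check_theta(theta)
    if k < 1:
        raise ValueError("moment order k must be >= 1")
    return 6.0 / ((k * theta + 2.0) * (k * theta + 3.0))


def mean(theta):
    """E(Y) = 6 / ((theta+2)(theta+3)); strictly decreasing in theta."""
    return raw_moment(1, theta)


def variance(theta):
    """Var(Y) in the printed rational form; equals E(Y^2) - E(Y)^2."""
    theta = _check_theta(theta)
    num = 3.0 * theta**2 * (theta**2 + 10.0 * theta + 13.0)
    den = (theta**2 + 5.0 * theta + 6.0) ** 2 * (2.0 * theta**2 + 5.0 * theta + 3.0)
    return num / den


def incomplete_moment(r: int, t, theta):
    """m_r(t) = E(Y^r 1{Y<=t}) = 6 t^(r+2/theta)/(r*theta+2) - 6 t^(r+3/theta)/(r*theta+3)."""
    theta = _check_theta(theta)
    if r < 1:
        raise ValueError("moment order r must be >= 1")
    t = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t <= 0.0) or np.any(t > 1.0):
        raise ValueError("truncation point t must lie in (0, 1]")
    return 6.0 * _pow(t, r + 2.0 / theta) / (r * theta + 2.0) - 6.0 * _pow(
        t, r + 3.0 / theta
    ) / (r * theta + 3.0)


def theta_from_mu(mu):
    """Shape parameter from the mean: theta = ((mu/(mu+24))^(-1/2) - 5)/2.

    Exact inverse of ``mu = 6/((theta+2)(theta+3))`` on mu in (0, 1);
    mu = 1/2 maps to theta = 1.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(~np.isfinite(mu)) or np.any(mu <= 0.0) or np.any(mu >= 1.0):
        raise ValueError("mu must lie strictly inside (0, 1)")
    return 0.5 * (np.sqrt((mu + 24.0) / mu) - 5.0)


def mu_from_theta(theta):
    """Mean from the shape parameter (alias of :func:`mean`)."""
    return mean(theta)


def expfam_components(theta) -> dict[str, Callable | float]:
    """One-parameter exponential-family decomposition of the density.

    f(y; theta) = exp[Q(theta) T(y) + D(theta) + S(y)] with
    Q = 2/theta - 1, T(y) = log y, D = log(6/theta),
    S(y) = log(1 - y^(1/theta)).  T is the sufficient statistic;
    S carries theta through the fixed power transform y^(1/theta).
    """
    theta = float(_check_theta(theta))
    return {
        "Q": 2.0 / theta - 1.0,
        "D": np.log(6.0 / theta),
        "T": lambda y: np.log(_check_open_unit(y, "y")),
        "S": lambda y: np.log1p(-_pow(_check_open_unit(y, "y"), 1.0 / theta)),
    }


def hrf_shape_diagnostic(theta, grid_size: int = 2001) -> str:
    """Numerical hazard-shape classification: 'increasing' or 'bathtub'.

    Counts sign changes of a finite-difference derivative of the hazard on
    an interior grid.  Offered as a diagnostic only; no closed-form boundary
    between the regimes is implemented.
    """
    y = np.linspace(1e-4, 1.0 - 1e-4, grid_size)
    h = hrf(y, theta)
    dh = np.diff(h)
    signs = np.sign(dh[np.abs(dh) > 1e-14])
    changes = int(np.count_nonzero(np.diff(signs) != 0))
    if changes == 0:
        return "increasing" if (signs.size == 0 or signs[-1] > 0) else "decreasing"
    return "bathtub" if changes == 1 else f"multimodal({changes})"
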