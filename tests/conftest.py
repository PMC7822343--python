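"""Shared fixtures and independent oracles.

The key cross-check used throughout: if B ~ Beta(2,2) then B**theta follows
the log-Bilal law with shape theta (the cdf 3y^(2/theta) - 2y^(3/theta) is
the Beta(2,2) cdf evaluated at y^(1/theta)).  scipy's beta distribution
therefore provides a fully independent oracle for the closed forms, and the
parent Bilal variable is the median of three i.i.d. exponentials.
"""

import numpy as np
import pytest
from scipy import stats


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def oracle_pdf(y, theta):
    """Density of B**theta, B ~ Beta(2,2), by change of variables."""
    y = np.asarray(y, dtype=float)
    b = y ** (1.0 / theta)
    return stats.beta(2, 2).pdf(b) * b / (theta * y)


def oracle_cdf(y, theta):
    return stats.beta(2, 2).cdf(np.asarray(y, dtype=float) ** (1.0 / theta))


def oracle_quantile(u, theta):
    return stats.beta(2, 2).ppf(u) ** theta


def sample_bilal_parent(n, theta, rng):
    """Bilal(theta) draws as the median of three i.i.d. Exp(scale theta)."""
    return np.median(rng.exponential(scale=theta, size=(n, 3)), axis=1)
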