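"""CSV readers and synthetic fixture generation.

The readers validate that responses land strictly inside (0, 1) after an
optional percent rescale (divide by 100) — rescaling is always an explicit
flag, never guessed from the data.  Fixture generation writes reproducible
samples and regression tables, with the generating truth in a JSON sidecar,
for tests, demos and external tooling.

The two applications this package was built around use the OECD Better Life
Index (2017 edition): the "dwellings without basic facilities" percentage as
a univariate sample, and "educational attainment" regressed on homicide
rate, dwellings without basic facilities and labor market insecurity.  That
extract is not redistributed here; download it from
https://stats.oecd.org (dataset code BLI) and save it as a CSV for
:func:`load_bli_table`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .distribution import UnitSample, quantile, theta_from_mu
from .regression import RegressionDesign

__all__ = [
    "DatasetSpec",
    "read_unit_table",
    "load_bli_table",
    "generate_sample_fixture",
    "generate_regression_fixture",
    "BLI_CSV_PATH",
]

logger = logging.getLogger(__name__)

#: default location for a user-supplied OECD Better Life Index 2017 extract
BLI_CSV_PATH = Path("data") / "oecd_bli_2017.csv"


@dataclass(frozen=True)
class DatasetSpec:
    path: Path
    response_column: str
    covariate_columns: tuple[str, ...] = ()
    percent_rescale: bool = False


def _validated_response(values: pd.Series, percent_rescale: bool) -> np.ndarray:
    y = values.to_numpy(dtype=float)
    if percent_rescale:
        y = y / 100.0
    bad = ~np.isfinite(y) | (y <= 0.0) | (y >= 1.0)
    if np.any(bad):
        row = int(values.index[np.flatnonzero(bad)[0]])
        raise ValueError(
            f"row {row}: response value {values.loc[row]!r} is outside the open "
            f"interval (0, 1){' after percent rescale' if percent_rescale else ''}"
        )
    return y


def read_unit_table(spec: DatasetSpec) -> UnitSample | RegressionDesign:
    """Read a CSV into a UnitSample (no covariates) or RegressionDesign.

    Rows with missing values in the used columns are dropped with a logged
    count; an intercept column is prepended for designs.
    """
    frame = pd.read_csv(spec.path)
    cols = [spec.response_column, *spec.covariate_columns]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"{spec.path}: columns not found: {missing}")
    for c in cols:
        if not pd.api.types.is_numeric_dtype(frame[c]):
            raise ValueError(f"{spec.path}: column {c!r} is not numeric")
    sub = frame[cols]
    kept = sub.dropna()
    if len(kept) < len(sub):
        logger.info("dropped %d rows with missing values", len(sub) - len(kept))
    if kept.empty:
        raise ValueError(f"{spec.path}: no complete rows remain")
    y = _validated_response(kept[spec.response_column], spec.percent_rescale)
    if not spec.covariate_columns:
        return UnitSample(y)
    X = np.column_stack(
        [np.ones(len(kept))] + [kept[c].to_numpy(dtype=float) for c in spec.covariate_columns]
    )
    return RegressionDesign(y, X, ["intercept", *spec.covariate_columns])


def load_bli_table(path: Path | str = BLI_CSV_PATH) -> pd.DataFrame:
    """Load a user-supplied OECD Better Life Index 2017 extract.

    Expected columns: ``country`` plus the percentage variables
    ``DWBF`` (dwellings without basic facilities), ``EA`` (educational
    attainment), ``HR`` (homicide rate) and ``LMI`` (labor market
    insecurity).  Raises FileNotFoundError with download guidance if absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found. The OECD Better Life Index (2017) extract is not "
            "redistributed with this package; download it from https://stats.oecd.org "
            "(dataset code BLI, 2017 edition) and save the columns country, DWBF, EA, "
            f"HR, LMI as {path}."
        )
    return pd.read_csv(path)


def generate_sample_fixture(
    path: Path | str, theta: float, n: int, seed: int
) -> Path:
    """Write n log-Bilal(theta) draws as a one-column CSV plus a JSON sidecar."""
    path = Path(path)
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    u[u == 0.0] = np.nextafter(0.0, 1.0)
    y = quantile(u, theta)
    pd.DataFrame({"y": y}).to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(
        json.dumps({"kind": "sample", "theta": theta, "n": n, "seed": seed}, indent=2)
    )
    return path


def generate_regression_fixture(
    path: Path | str,
    beta: list[float],
    n: int,
    seed: int,
    covariate_dist: str = "uniform",
) -> Path:
    """Write a synthetic regression table with a log-Bilal response.

    Covariates (one per slope coefficient) are drawn i.i.d. from U(0,1) or
    the standard normal; mu_i = expit(x_i' beta), and the response is an
    inverse-transform draw at shape theta(mu_i).  The generating
    coefficients and seed go in a JSON sidecar.
    """
    path = Path(path)
    beta = np.asarray(beta, dtype=float)
    rng = np.random.default_rng(seed)
    p = beta.size
    if covariate_dist == "uniform":
        X = rng.uniform(size=(n, p - 1))
    elif covariate_dist == "normal":
        X = rng.standard_normal(size=(n, p - 1))
    else:
        raise ValueError("covariate_dist must be 'uniform' or 'normal'")
    design = np.column_stack([np.ones(n), X])
    mu = special.expit(design @ beta)
    u = rng.uniform(size=n)
    u[u == 0.0] = np.nextafter(0.0, 1.0)
    y = quantile(u, theta_from_mu(mu))
    cols = {"y": y}
    for j in range(p - 1):
        cols[f"x{j + 1}"] = X[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(
        json.dumps(
            {
                "kind": "regression",
                "beta": beta.tolist(),
                "n": n,
                "seed": seed,
                "covariate_dist": covariate_dist,
            },
            indent=2,
        )
    )
    return path
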