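"""Climate sensitivity: the tangent of the fitted response curve at mean climate.

For a (possibly quadratic) response B = b1*x + b2*x^2 in centred climate x,
the sensitivity is the first derivative evaluated at the mean climate,

    s = b1 + 2 * b2 * cbar,

with delta-method variance

    Var(s) = Var(b1) + 4*cbar^2*Var(b2) + 4*cbar*Cov(b1, b2).

Because model fits centre climate on its grand mean (over all site-years),
the tangent at the mean is evaluated at cbar = 0, i.e. s = b1; the general
form supports tangents at other climate values. Gram-scale sensitivities are
rescaled to percent of species mean mass for cross-species comparison, and
sites observed only under one-sided climate (every year strictly above, or
strictly below, the grand mean) are excluded to avoid extrapolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SensitivityEstimate:
    level: str                 # "species" or "site"
    species: str
    variable: str
    site: str | None = None
    cbar: float = 0.0          # climate value at which the tangent is taken (centred scale)
    s_gram: float = 0.0        # g per climate unit
    se_gram: float = 0.0
    s_pct: float = 0.0         # % of species mean mass per climate unit
    se_pct: float = 0.0
    n_years: int = 0


def tangent_at_mean(
    beta1: float, beta2: float, cov: np.ndarray, cbar: float = 0.0
) -> tuple[float, float]:
    """Tangent slope of b1*x + b2*x^2 at x = cbar, with delta-method SE.

    ``cov`` is the 2x2 covariance of (b1, b2); for a linear fit pass b2 = 0
    with zero second row/column.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError("cov must be 2x2")
    s = beta1 + 2.0 * beta2 * cbar
    var = cov[0, 0] + 4.0 * cbar**2 * cov[1, 1] + 4.0 * cbar * cov[0, 1]
    return float(s), float(np.sqrt(max(var, 0.0)))


def to_percent(s_gram: float, mean_mass: float) -> float:
    """Rescale a gram-scale sensitivity to percent of species mean mass."""
    if mean_mass <= 0:
        raise ValueError("mean mass must be positive")
    return 100.0 * s_gram / mean_mass


def filter_extrapolating_sites(site_year_climate: pd.DataFrame) -> tuple[list[str], pd.DataFrame]:
    """Drop sites observed only on one side of the grand-mean climate.

    ``site_year_climate`` has columns site, year, value; the grand mean is
    the equally weighted mean over all site-years. A site is excluded when
    every one of its yearly aggregates is strictly above, or strictly below,
    that grand mean (a year exactly at the mean keeps the site). Returns the
    retained site ids and an exclusion log.
    """
    grand = site_year_climate["value"].mean()
    retained, log_rows = [], []
    for site, grp in site_year_climate.groupby("site"):
        v = grp["value"].to_numpy(float)
        if (v > grand).all():
            log_rows.append({"site": site, "reason": "all years above grand mean"})
        elif (v < grand).all():
            log_rows.append({"site": site, "reason": "all years below grand mean"})
        else:
            retained.append(site)
    if log_rows:
        logger.info("excluded %d extrapolating sites", len(log_rows))
    return retained, pd.DataFrame(log_rows, columns=["site", "reason"])


def sensitivity_table(estimates: list[SensitivityEstimate]) -> pd.DataFrame:
    """Tidy CSV-ready table of sensitivity estimates."""
    return pd.DataFrame(
        [
            {
                "level": e.level,
                "species": e.species,
                "site": e.site,
                "variable": e.variable,
                "cbar": e.cbar,
                "s_gram": e.s_gram,
                "se_gram": e.se_gram,
                "s_pct": e.s_pct,
                "se_pct": e.se_pct,
                "n_years": e.n_years,
            }
            for e in estimates
        ]
    )


def make_estimate(
    level: str,
    species: str,
    variable: str,
    beta1: float,
    beta2: float,
    cov: np.ndarray,
    mean_mass: float,
    site: str | None = None,
    cbar: float = 0.0,
    n_years: int = 0,
) -> SensitivityEstimate:
    """Convenience constructor: tangent + percent scaling in one step."""
    s, se = tangent_at_mean(beta1, beta2, cov, cbar)
    return SensitivityEstimate(
        level=level,
        species=species,
        site=site,
        variable=variable,
        cbar=cbar,
        s_gram=s,
        se_gram=se,
        s_pct=to_percent(s, mean_mass),
        se_pct=to_percent(se, mean_mass),
        n_years=n_years,
    )
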