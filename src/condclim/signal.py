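"""The species signal: among-species vs among-population variance of responses.

Site-level sensitivity estimates (one per species x site, with standard
errors) are decomposed by an intercept-only weighted random-intercept model
with species as the grouping factor. The ratio

    sigma2_species / (sigma2_species + sigma2_population)

is the intraclass correlation: near 1, populations of the same species
respond alike (a strong species signal); near 0, populations of one species
differ as much as populations of different species and a single species-
level response value is not meaningful. Observations are weighted by the
inverse standard error of the estimates (the literal published scheme;
inverse-variance weighting is available as a config switch). A diagnostic
regression checks whether sampling variance (sites sampled in few years)
inflates the residual component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import aicc, gaussian_loglik
from .mixed import fit_weighted_random_intercept

logger = logging.getLogger(__name__)


@dataclass
class VarianceDecomposition:
    variable: str              # climate variable, or "projection"
    sigma2_species: float
    sigma2_population: float
    ratio: float               # intraclass correlation, in [0, 1]
    n_species: int
    n_estimates: int
    weighting: str

    def __post_init__(self):
        if not (0.0 <= self.ratio <= 1.0):
            raise ValueError(f"ratio must be in [0, 1], got {self.ratio}")


def species_exclusion_filter(site_estimates: pd.DataFrame, min_sites: int = 7) -> pd.DataFrame:
    """Drop species represented at fewer than ``min_sites`` sites."""
    counts = site_estimates.groupby("species")["site"].nunique()
    keep = counts[counts >= min_sites].index
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        logger.info("excluding %d species with < %d sites: %s", len(dropped), min_sites, dropped)
    return site_estimates[site_estimates["species"].isin(keep)].reset_index(drop=True)


def fit_variance_components(
    site_estimates: pd.DataFrame,
    variable: str = "sensitivity",
    weighting: str = "inverse-se",
    min_species: int = 5,
    min_sites_per_species: int = 2,
) -> VarianceDecomposition:
    """Weighted REML variance decomposition of site-level estimates.

    ``site_estimates`` needs columns species, site, estimate, se.
    ``weighting`` is "inverse-se" (w = 1/SE, the published scheme),
    "inverse-variance" (w = 1/SE^2) or "none". Variance components are
    bounded at zero.
    """
    df = site_estimates.dropna(subset=["estimate"]).copy()
    counts = df.groupby("species")["site"].nunique()
    ok = counts[counts >= min_sites_per_species].index
    df = df[df["species"].isin(ok)]
    if df["species"].nunique() < min_species:
        raise ValueError(
            f"need >= {min_species} species with >= {min_sites_per_species} "
            f"sites each, have {df['species'].nunique()}"
        )
    if weighting == "inverse-se":
        w = 1.0 / df["se"].to_numpy(float)
    elif weighting == "inverse-variance":
        w = 1.0 / df["se"].to_numpy(float) ** 2
    elif weighting == "none":
        w = None
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    fit = fit_weighted_random_intercept(
        df["estimate"].to_numpy(float),
        np.ones((len(df), 1)),
        df["species"].to_numpy(),
        weights=w,
        method="reml",
    )
    s2_sp = max(fit.sigma2_group, 0.0)
    s2_pop = max(fit.sigma2_resid, 0.0)
    total = s2_sp + s2_pop
    return VarianceDecomposition(
        variable=variable,
        sigma2_species=s2_sp,
        sigma2_population=s2_pop,
        ratio=s2_sp / total if total > 0 else 0.0,
        n_species=int(df["species"].nunique()),
        n_estimates=len(df),
        weighting=weighting,
    )


def sampling_variance_check(site_estimates: pd.DataFrame, years_col: str = "n_years") -> float:
    """Does estimate scatter depend on how many years a site was sampled?

    Regresses the absolute deviation of each site estimate from its species
    mean on a quadratic in years sampled, and returns
    AICc(null) - AICc(quadratic): positive values support a relationship,
    i.e. sampling variance inflating the population variance component.
    """
    df = site_estimates.dropna(subset=["estimate", years_col]).copy()
    sp_mean = df.groupby("species")["estimate"].transform("mean")
    dev = (df["estimate"] - sp_mean).abs().to_numpy(float)
    yrs = df[years_col].to_numpy(float)
    n = len(df)

    def _ols_aicc(X):
        coef, *_ = np.linalg.lstsq(X, dev, rcond=None)
        rss = float(((dev - X @ coef) ** 2).sum())
        return aicc(gaussian_loglik(rss, n), X.shape[1] + 1, n)

    a_null = _ols_aicc(np.ones((n, 1)))
    a_quad = _ols_aicc(np.column_stack([np.ones(n), yrs, yrs**2]))
    return a_null - a_quad


def decomposition_table(decomps: list[VarianceDecomposition]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": d.variable,
                "sigma2_species": d.sigma2_species,
                "sigma2_population": d.sigma2_population,
                "ratio": d.ratio,
                "n_species": d.n_species,
                "n_estimates": d.n_estimates,
                "weighting": d.weighting,
            }
            for d in decomps
        ]
    )
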