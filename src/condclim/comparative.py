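"""Trait, phylogeny and geography as predictors of climate responses.

Species-level hypotheses (body size, migration strategy, habitat
preference, life-expectancy) and site-level hypotheses (habitat wet/dry,
population density) are each tested by regressing sensitivities or
projections on the trait — weighted by inverse standard error, with a
species random intercept at site level — and comparing AICc against an
intercept-only null. Pairwise phylogenetic distance (divergence time, Myr)
and geographic distance (km) are related to response dissimilarity (the
absolute difference of two estimates) by OLS; because such pairwise
regressions ignore the non-independence of pairs, a Mantel-style
permutation p-value is reported alongside as a diagnostic. Whether two
species are affected by the same climate variables is related to their
divergence time by logistic regression.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from ._stats import aicc
from .ingest import haversine_km
from .mixed import fit_weighted_random_intercept

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# trait models


@dataclass
class TraitModelResult:
    trait: str
    level: str                     # "species" or "site"
    response: str
    coef: np.ndarray
    se: np.ndarray
    term_names: list[str]
    aicc_model: float
    aicc_null: float

    @property
    def delta_aicc(self) -> float:
        """AICc(trait model) - AICc(null); negative favours the trait."""
        return self.aicc_model - self.aicc_null


def fit_trait_model(
    estimates: pd.DataFrame,
    trait: str,
    level: str = "species",
    response: str = "sensitivity",
    weighting: str = "inverse-se",
) -> TraitModelResult:
    """Weighted regression of response estimates on one trait vs a null model.

    ``estimates`` needs columns estimate, se, the trait column, and species
    (plus site at site level, where species enters as a random intercept).
    """
    df = estimates.dropna(subset=["estimate", trait]).copy()
    if df[trait].nunique() < 2:
        raise ValueError(f"trait {trait!r} has a single level; model inestimable")
    y = df["estimate"].to_numpy(float)
    n = len(df)
    if weighting == "inverse-se":
        w = 1.0 / df["se"].to_numpy(float)
    elif weighting == "inverse-variance":
        w = 1.0 / df["se"].to_numpy(float) ** 2
    elif weighting == "none":
        w = np.ones(n)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    rhs = f"C(Q('{trait}'))" if df[trait].dtype == object else f"Q('{trait}')"
    X = patsy.dmatrix("1 + " + rhs, df, return_type="dataframe")
    names = list(X.columns)
    X = np.asarray(X)
    X0 = np.ones((n, 1))

    if level == "species":
        fit = sm.WLS(y, X, weights=w).fit()
        null = sm.WLS(y, X0, weights=w).fit()
        a_model = aicc(float(fit.llf), X.shape[1] + 1, n)
        a_null = aicc(float(null.llf), 2, n)
        coef, se = np.asarray(fit.params), np.asarray(fit.bse)
    elif level == "site":
        groups = df["species"].to_numpy()
        fit = fit_weighted_random_intercept(y, X, groups, weights=w, method="ml")
        null = fit_weighted_random_intercept(y, X0, groups, weights=w, method="ml")
        a_model = aicc(fit.llf, X.shape[1] + 2, n)
        a_null = aicc(null.llf, 3, n)
        coef = fit.beta
        se = np.sqrt(np.clip(np.diag(fit.cov_beta), 0, None))
    else:
        raise ValueError("level must be 'species' or 'site'")
    return TraitModelResult(
        trait=trait,
        level=level,
        response=response,
        coef=coef,
        se=se,
        term_names=names,
        aicc_model=a_model,
        aicc_null=a_null,
    )


# ---------------------------------------------------------------------------
# distances


def phylo_distance(tree: dendropy.Tree, species: list[str] | None = None) -> pd.DataFrame:
    """Pairwise divergence times (Myr): half the patristic tip-to-tip distance.

    On an ultrametric tree the patristic distance between two tips is twice
    their time since divergence.
    """
    labels = {t.label for t in tree.taxon_namespace}
    if species is not None:
        missing = sorted(set(species) - labels)
        if missing:
            raise ValueError(f"species missing from tree: {missing}")
        wanted = set(species)
    else:
        wanted = labels
    pdm = tree.phylogenetic_distance_matrix()
    rows = []
    taxa = sorted((t for t in tree.taxon_namespace if t.label in wanted),
                  key=lambda t: t.label)
    for t1, t2 in itertools.combinations(taxa, 2):
        rows.append(
            {"a": t1.label, "b": t2.label,
             "distance": 0.5 * float(pdm.patristic_distance(t1, t2))}
        )
    return pd.DataFrame(rows)


def geo_distance(sites: pd.DataFrame) -> pd.DataFrame:
    """Pairwise great-circle distances (km) between sites with lat/lon."""
    if sites[["lat", "lon"]].isna().any().any():
        raise ValueError("missing site coordinates")
    rows = []
    recs = sites.sort_values("site").itertuples()
    recs = list(recs)
    for r1, r2 in itertools.combinations(recs, 2):
        rows.append(
            {
                "a": r1.site,
                "b": r2.site,
                "distance": float(haversine_km(r1.lat, r1.lon, r2.lat, r2.lon)),
            }
        )
    return pd.DataFrame(rows)


def dissimilarity_pairs(estimates: pd.DataFrame, id_col: str, distances: pd.DataFrame) -> pd.DataFrame:
    """Join |estimate_a - estimate_b| onto a pairwise distance table."""
    vals = estimates.set_index(id_col)["estimate"]
    df = distances.copy()
    df["dissimilarity"] = [
        abs(float(vals[a]) - float(vals[b])) for a, b in zip(df["a"], df["b"])
    ]
    return df


# ---------------------------------------------------------------------------
# distance-dissimilarity regression


@dataclass
class DistanceRegressionResult:
    slope: float
    se: float
    ci_low: float
    ci_high: float
    n_pairs: int
    significant_positive: bool
    mantel_p: float | None = None  # permutation diagnostic, not part of the published analysis


def distance_dissimilarity_regression(
    pairs: pd.DataFrame,
    n_perm: int = 0,
    seed: int = 0,
) -> DistanceRegressionResult:
    """OLS slope of dissimilarity on distance, flagging significant-positive.

    The OLS inference treats pairs as independent, exactly as the published
    procedure does. With ``n_perm`` > 0 a Mantel-style permutation p-value
    (relabelling the underlying units) is computed as a diagnostic.
    """
    if len(pairs) < 3:
        raise ValueError("need >= 3 pairs")
    x = pairs["distance"].to_numpy(float)
    y = pairs["dissimilarity"].to_numpy(float)
    if np.std(x) < 1e-15:
        raise ValueError("zero-variance distances")
    X = np.column_stack([np.ones_like(x), x])
    fit = sm.OLS(y, X).fit()
    slope, se = float(fit.params[1]), float(fit.bse[1])
    lo, hi = slope - _Z95 * se, slope + _Z95 * se
    mantel_p = None
    if n_perm > 0:
        ids = sorted(set(pairs["a"]) | set(pairs["b"]))
        rng = np.random.default_rng(np.random.SeedSequence([seed, 700]))
        obs = abs(slope)
        count = 0
        for _ in range(n_perm):
            perm = dict(zip(ids, rng.permutation(ids)))
            pa = pairs["a"].map(perm)
            pb = pairs["b"].map(perm)
            key = pd.DataFrame({"a": np.minimum(pa, pb), "b": np.maximum(pa, pb)})
            lut = pairs.assign(
                a=np.minimum(pairs["a"], pairs["b"]), b=np.maximum(pairs["a"], pairs["b"])
            ).set_index(["a", "b"])["dissimilarity"]
            yp = lut.loc[list(key.itertuples(index=False))].to_numpy(float)
            sp = float(sm.OLS(yp, X).fit().params[1])
            if abs(sp) >= obs:
                count += 1
        mantel_p = (1 + count) / (n_perm + 1)
    return DistanceRegressionResult(
        slope=slope,
        se=se,
        ci_low=lo,
        ci_high=hi,
        n_pairs=len(pairs),
        significant_positive=bool(slope > 0 and lo > 0),
        mantel_p=mantel_p,
    )


# ---------------------------------------------------------------------------
# concordance of affected-variable sets vs phylogeny


@dataclass
class ConcordanceResult:
    variable: str
    slope: float | None
    se: float | None
    n_pairs: int
    separation: bool               # all pairs concordant (or discordant): slope undefined


def concordance_vs_phylo(
    affected: pd.DataFrame, phylo_pairs: pd.DataFrame, variable: str = ""
) -> ConcordanceResult:
    """Logistic regression of same-status indicator on divergence time.

    ``affected`` has columns species, affected (bool: window-scan signal at
    p < alpha). For each species pair the indicator is 1 when both share the
    same status. A negative slope means closely related species are more
    concordant.
    """
    status = affected.set_index("species")["affected"].astype(bool)
    df = phylo_pairs.copy()
    df["same"] = [
        int(status[a] == status[b]) for a, b in zip(df["a"], df["b"])
    ]
    if df["same"].nunique() < 2:
        logger.info("concordance for %s: complete separation (all pairs alike)", variable)
        return ConcordanceResult(variable, None, None, len(df), separation=True)
    X = np.column_stack([np.ones(len(df)), df["distance"].to_numpy(float)])
    try:
        fit = sm.Logit(df["same"].to_numpy(), X).fit(disp=0)
    except Exception as exc:  # perfect separation along distance
        logger.info("concordance for %s: %s", variable, exc)
        return ConcordanceResult(variable, None, None, len(df), separation=True)
    return ConcordanceResult(
        variable=variable,
        slope=float(fit.params[1]),
        se=float(fit.bse[1]),
        n_pairs=len(df),
        separation=False,
    )
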