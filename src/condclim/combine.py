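"""Multi-climate model: all-subsets AICc selection, averaging, site slopes.

After the per-variable window scans, the signal-bearing variables (each at
its best window and selected shape) are combined in a single body-condition
model. Candidate models are every subset of the climate variables — with
collinear variables (|r| > 0.6 on their window aggregates, transitive
closure) entering and leaving as one group — always on top of the fixed
baseline covariates. Variables absent from every model within 2 AICc of the
best are excluded, as are "hitchhiker" variables that ride along in top
models without improving the likelihood. Coefficients of the survivors are
full (zero-substituted) Akaike-weight averages over the top model set, with
unconditional variances combining within-model variance and between-model
spread. Site-specific slopes come from refitting the retained models with
fixed site x climate interaction terms and averaging the same way.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy

from ._stats import aicc, akaike_weights, gaussian_loglik
from .windows import DEFAULT_BASELINE, WindowScanResult, _series_map

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# collinearity grouping


def collinear_groups(aggregates: pd.DataFrame, threshold: float = 0.6) -> list[list[str]]:
    """Partition climate variables into collinearity groups.

    ``aggregates`` has one column per variable of per-site-year window
    aggregates. Variables with pairwise Pearson |r| > threshold are joined,
    with transitive closure, so correlated variables always enter candidate
    models together.
    """
    cols = list(aggregates.columns)
    if (aggregates.std(ddof=0) < 1e-12).any():
        bad = aggregates.columns[aggregates.std(ddof=0) < 1e-12].tolist()
        raise ValueError(f"zero-variance window aggregate(s): {bad}")
    r = aggregates.corr().abs().to_numpy()
    parent = list(range(len(cols)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if r[i, j] > threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i, c in enumerate(cols):
        groups.setdefault(find(i), []).append(c)
    return sorted(groups.values())


# ---------------------------------------------------------------------------
# model containers


@dataclass
class FittedModel:
    variables: tuple[str, ...]          # climate variables included
    k: int
    llf: float
    aicc: float
    coefs: dict = field(default_factory=dict)   # key -> [b1, b2]
    covs: dict = field(default_factory=dict)    # key -> 2x2 covariance


@dataclass
class ModelSet:
    models: list[FittedModel]
    n: int

    def table(self) -> pd.DataFrame:
        a = np.array([m.aicc for m in self.models])
        w = akaike_weights(a)
        return pd.DataFrame(
            {
                "subset": ["+".join(m.variables) or "(null)" for m in self.models],
                "k": [m.k for m in self.models],
                "logLik": [m.llf for m in self.models],
                "AICc": a,
                "dAICc": a - a.min(),
                "weight": w,
            }
        ).sort_values("AICc", kind="stable", ignore_index=True)

    def best(self) -> FittedModel:
        return min(self.models, key=lambda m: m.aicc)


@dataclass
class AveragedModel:
    coefficients: dict                  # key -> [b1, b2] averaged
    covariances: dict                   # key -> 2x2 unconditional covariance
    retained: list[str]
    excluded: list[tuple[str, str]]     # (variable, reason)
    weights: np.ndarray                 # Akaike weights over the top set
    top_models: list[FittedModel]
    centers: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# design construction


def climate_columns(
    condition: pd.DataFrame,
    climate,
    scans: dict[str, WindowScanResult],
    site_to_station: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Per-row centred window aggregates for the scanned variables.

    Returns (row-level table with one column per variable, site-year level
    aggregate table, per-variable grand means used for centring).
    """
    cond = condition.copy()
    if "year" not in cond.columns:
        cond["year"] = pd.DatetimeIndex(cond["date"]).year
    sy = cond[["site", "year"]].drop_duplicates().reset_index(drop=True)
    from .windows import aggregate_window
    from .ingest import reference_date

    per_row = pd.DataFrame(index=cond.index)
    per_sy = sy.copy()
    centers: dict[str, float] = {}
    for var, scan in scans.items():
        series_map = _series_map(climate, var)
        vals = []
        for r in sy.itertuples():
            st = (
                site_to_station[r.site]
                if site_to_station is not None
                else next(iter(series_map))
            )
            agg = aggregate_window(
                series_map[st], scan.window, [pd.Timestamp(reference_date(int(r.year)))]
            )
            vals.append(float(agg.iloc[0]))
        vals = np.asarray(vals)
        centers[var] = float(vals.mean())
        per_sy[var] = vals - centers[var]
        merged = cond.merge(per_sy[["site", "year", var]], on=["site", "year"], how="left")
        per_row[var] = merged[var].to_numpy()
    return per_row, per_sy, centers


# ---------------------------------------------------------------------------
# fitting engines


def _fit(y, X, groups, method, extra_k=0):
    """Fit one candidate model; returns (params, cov, llf, k)."""
    n, p = X.shape
    if method == "ols":
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        rss = float(resid @ resid)
        llf = gaussian_loglik(rss, n)
        XtX_inv = np.linalg.pinv(X.T @ X)
        sigma2 = rss / max(n - p, 1)
        cov = sigma2 * XtX_inv
        k = p + 1
    else:
        from statsmodels.regression.mixed_linear_model import MixedLM

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = MixedLM(y, X, groups=groups).fit(reml=False)
        coef = np.asarray(fit.fe_params)
        cov = np.asarray(fit.cov_params())[:p, :p]
        llf = float(fit.llf)
        k = p + 2
    return coef, cov, llf, k + extra_k


def _assemble(
    X0: np.ndarray,
    per_row: pd.DataFrame,
    shapes: dict[str, str],
    variables: list[str],
    site_dummies: np.ndarray | None = None,
    site_ids: list[str] | None = None,
):
    """Design matrix for a subset of variables, plus coefficient key layout.

    Without site interactions, each variable contributes x (and x^2 when
    quadratic) and keys are variable names. With ``site_dummies``, each
    variable contributes one slope (pair) per site and keys are
    (variable, site) tuples.
    """
    cols, keys = [], []  # keys[i] = (key, which) with which in {0 (b1), 1 (b2)}
    for var in variables:
        x = per_row[var].to_numpy(float)
        quad = shapes[var] == "quadratic"
        if site_dummies is None:
            cols.append(x)
            keys.append((var, 0))
            if quad:
                cols.append(x**2)
                keys.append((var, 1))
        else:
            for si, site in enumerate(site_ids):
                cols.append(x * site_dummies[:, si])
                keys.append(((var, site), 0))
            if quad:
                for si, site in enumerate(site_ids):
                    cols.append(x**2 * site_dummies[:, si])
                    keys.append(((var, site), 1))
    X = np.column_stack([X0] + cols) if cols else X0
    return X, keys


def _extract(coef, cov, keys, p0):
    """Pull per-key [b1, b2] and 2x2 covariance blocks out of a fit."""
    idx: dict[object, dict[int, int]] = {}
    for j, (key, which) in enumerate(keys):
        idx.setdefault(key, {})[which] = p0 + j
    coefs, covs = {}, {}
    for key, m in idx.items():
        b = np.zeros(2)
        C = np.zeros((2, 2))
        for wi, j in m.items():
            b[wi] = coef[j]
            C[wi, wi] = cov[j, j]
        if 0 in m and 1 in m:
            C[0, 1] = C[1, 0] = cov[m[0], m[1]]
        coefs[key] = b
        covs[key] = C
    return coefs, covs


# ---------------------------------------------------------------------------
# all-subsets selection


def all_subsets(
    condition: pd.DataFrame,
    per_row: pd.DataFrame,
    shapes: dict[str, str],
    groups: list[list[str]],
    baseline: str = DEFAULT_BASELINE,
    method: str = "ols",
    site_interactions: bool = False,
) -> ModelSet:
    """Fit every subset of variable groups on top of the baseline model.

    Shapes (linear/quadratic) are frozen from the scan stage. With
    ``site_interactions`` the climate slopes are site-specific fixed
    effects (site main effects are then also added to the baseline), and
    sites observed in a single year are dropped with a log entry.
    """
    if len(groups) > 6:
        raise ValueError("more than 6 variable groups (2^k model space too large)")
    cond = condition.reset_index(drop=True)
    per_row = per_row.reset_index(drop=True)
    if site_interactions:
        if "year" not in cond.columns:
            cond = cond.assign(year=pd.DatetimeIndex(cond["date"]).year)
        ny = cond.groupby("site")["year"].nunique()
        single = ny[ny < 2].index.tolist()
        if single:
            logger.info("dropping single-year sites from interaction fit: %s", single)
            keep = ~cond["site"].isin(single)
            cond = cond[keep].reset_index(drop=True)
            per_row = per_row[keep.to_numpy()].reset_index(drop=True)
        if cond["site"].nunique() < 2:
            raise ValueError("need >= 2 sites for site x climate interactions")

    X0 = np.asarray(patsy.dmatrix(baseline, cond, return_type="dataframe"))
    site_dummies = site_ids = None
    if site_interactions:
        site_ids = sorted(cond["site"].unique())
        site_dummies = (cond["site"].to_numpy()[:, None] == np.array(site_ids)).astype(float)
        # site main effects (drop first level; intercept already present)
        X0 = np.column_stack([X0, site_dummies[:, 1:]])
    y = cond["condition"].to_numpy(float)
    grp = cond["individual"].to_numpy() if "individual" in cond else np.arange(len(y))
    n, p0 = X0.shape

    models = []
    for r in range(len(groups) + 1):
        for combo in itertools.combinations(range(len(groups)), r):
            variables = [v for gi in combo for v in groups[gi]]
            X, keys = _assemble(X0, per_row, shapes, variables, site_dummies, site_ids)
            if n <= X.shape[1] + 2:
                logger.warning("dropping subset %s: n too small for k", variables)
                continue
            try:
                coef, cov, llf, k = _fit(y, X, grp, method)
            except Exception as exc:
                logger.warning("subset %s failed to fit: %s", variables, exc)
                continue
            coefs, covs = _extract(coef, cov, keys, p0)
            models.append(
                FittedModel(
                    variables=tuple(variables),
                    k=k,
                    llf=llf,
                    aicc=aicc(llf, k, n),
                    coefs=coefs,
                    covs=covs,
                )
            )
    if not models:
        raise RuntimeError("no candidate model could be fitted")
    return ModelSet(models=models, n=n)


# ---------------------------------------------------------------------------
# pruning + full model averaging


def _average(top: list[FittedModel], w: np.ndarray, keys: list) -> tuple[dict, dict]:
    """Full (zero-substituted) averages and unconditional covariances."""
    coefs, covs = {}, {}
    for key in keys:
        bs = np.array([m.coefs.get(key, np.zeros(2)) for m in top])
        Cs = np.array([m.covs.get(key, np.zeros((2, 2))) for m in top])
        bbar = w @ bs
        dev = bs - bbar
        Cu = np.einsum("m,mij->ij", w, Cs) + np.einsum("m,mi,mj->ij", w, dev, dev)
        coefs[key] = bbar
        covs[key] = Cu
    return coefs, covs


def prune_and_average(
    model_set: ModelSet,
    delta: float = 2.0,
    hitchhiker_llf: float = 1.0,
    centers: dict[str, float] | None = None,
) -> AveragedModel:
    """Exclude uninformative variables and average the rest.

    The top set is every model within ``delta`` AICc of the best. A variable
    absent from all top-set models is excluded (not-in-top-set). A variable
    is a hitchhiker when the best top-set model containing it beats the best
    top-set model without it by less than ``hitchhiker_llf`` log-likelihood
    units AND its averaged 95% CI spans zero. Survivors get full
    (zero-substituted) Akaike-weight averages with unconditional variances.
    """
    a = np.array([m.aicc for m in model_set.models])
    top = [m for m, ai in zip(model_set.models, a) if ai - a.min() <= delta]
    w = akaike_weights(np.array([m.aicc for m in top]))
    all_vars = sorted({v for m in model_set.models for v in m.variables})

    excluded: list[tuple[str, str]] = []
    present = sorted({v for m in top for v in m.variables})
    for v in all_vars:
        if v not in present:
            excluded.append((v, "not-in-top-set"))

    # averages over the top set for the variables present there
    keys = sorted({k for m in top for k in m.coefs})
    coefs, covs = _average(top, w, keys)

    retained = []
    for v in present:
        with_v = [m.llf for m in top if v in m.variables]
        without_v = [m.llf for m in top if v not in m.variables]
        is_hitch = False
        if without_v:
            gain = max(with_v) - max(without_v)
            if gain < hitchhiker_llf:
                b = coefs.get(v, np.zeros(2))
                C = covs.get(v, np.zeros((2, 2)))
                ses = np.sqrt(np.clip(np.diag(C), 0, None))
                spans_zero = all(
                    abs(b[i]) <= 1.959963984540054 * ses[i] if ses[i] > 0 else b[i] == 0
                    for i in range(2)
                )
                is_hitch = spans_zero
        if is_hitch:
            excluded.append((v, "hitchhiker"))
        else:
            retained.append(v)

    coefs = {k: v for k, v in coefs.items() if _root_var(k) in retained}
    covs = {k: v for k, v in covs.items() if _root_var(k) in retained}
    logger.info("retained %s; excluded %s", retained, excluded)
    return AveragedModel(
        coefficients=coefs,
        covariances=covs,
        retained=retained,
        excluded=excluded,
        weights=w,
        top_models=top,
        centers=dict(centers or {}),
    )


def _root_var(key) -> str:
    return key[0] if isinstance(key, tuple) else key


def site_interaction_fit(
    condition: pd.DataFrame,
    per_row: pd.DataFrame,
    shapes: dict[str, str],
    retained: list[str],
    groups: list[list[str]],
    baseline: str = DEFAULT_BASELINE,
    method: str = "ols",
    delta: float = 2.0,
) -> AveragedModel:
    """Model-averaged site-specific climate slopes.

    Refits every subset of the retained variable groups with fixed
    site x climate (and site x climate^2 for quadratic shapes) interactions
    and averages per-site coefficients over the top set, substituting zero
    where a variable is absent. Keys of the result are (variable, site).
    """
    kept_groups = [g for g in groups if any(v in retained for v in g)]
    ms = all_subsets(
        condition,
        per_row,
        shapes,
        kept_groups,
        baseline=baseline,
        method=method,
        site_interactions=True,
    )
    a = np.array([m.aicc for m in ms.models])
    top = [m for m, ai in zip(ms.models, a) if ai - a.min() <= delta]
    w = akaike_weights(np.array([m.aicc for m in top]))
    keys = sorted({k for m in top for k in m.coefs if _root_var(k) in retained})
    coefs, covs = _average(top, w, keys)
    return AveragedModel(
        coefficients=coefs,
        covariances=covs,
        retained=list(retained),
        excluded=[],
        weights=w,
        top_models=top,
    )
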