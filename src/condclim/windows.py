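"""Exhaustive climate-window scan for one species and one climate variable.

Every consecutive-day window within the 365 days before the 15 August
reference date is a candidate: the daily series is averaged over the window
per site-year, grand-mean centred, and added (linearly or quadratically) to
a baseline body-condition model with the capture covariates. The (window,
shape) pair minimizing AICc wins; ties break to shorter, then more recent
windows, then to the linear shape. A year-permutation randomization test
guards against the best window being an artefact of trying tens of
thousands of models.

Two fitting engines are available. The fixed-effects engine solves every
candidate by ordinary least squares through Frisch-Waugh residualization,
vectorized across all windows at once (exact, and identical to the mixed
model when no individual is recaptured). The mixed engine fits a per-
candidate linear mixed model with an individual random intercept
(statsmodels MixedLM, ML) and is the faithful choice for recapture-heavy
data at a substantial speed cost.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy

from ._stats import aicc, gaussian_loglik
from .ingest import reference_date

logger = logging.getLogger(__name__)

#: covariates of the baseline body-condition model (patsy formula RHS)
DEFAULT_BASELINE = (
    "C(age) + C(sex) + time + I(time**2) + day_of_season + I(day_of_season**2)"
)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# candidate windows


def enumerate_windows(max_lag: int = 365, stride: int = 1) -> list[tuple[int, int]]:
    """All (start_offset, end_offset) pairs with start >= end, on the stride grid.

    Offsets are inclusive days before the reference date (offset 1 = the day
    before). For stride 1 and max_lag 365 this is 365*366/2 = 66,795 windows.
    """
    if max_lag < 1 or stride < 1:
        raise ValueError("max_lag and stride must be >= 1")
    grid = range(stride, max_lag + 1, stride)
    return [(s, e) for s in grid for e in grid if s >= e]


def aggregate_window(
    series: pd.Series, window: tuple[int, int], reference_dates
) -> pd.Series:
    """Mean daily value in the inclusive offset window before each reference date.

    ``series`` is date-indexed daily data; raises if any day in the window
    range is missing, naming the gap.
    """
    start, end = window
    if not (start >= end >= 1):
        raise ValueError(f"invalid window {window}")
    series = series.sort_index()
    out = {}
    for ref in reference_dates:
        ref = pd.Timestamp(ref)
        days = pd.date_range(ref - pd.Timedelta(days=start), ref - pd.Timedelta(days=end))
        chunk = series.reindex(days)
        if chunk.isna().any():
            gap = chunk.index[chunk.isna()][0].date()
            raise ValueError(f"missing climate value on {gap} for reference {ref.date()}")
        out[ref] = float(chunk.mean())
    return pd.Series(out)


# ---------------------------------------------------------------------------
# result container


@dataclass
class WindowScanResult:
    window: tuple[int, int]
    shape: str                     # "linear" or "quadratic"
    beta1: float
    beta2: float
    cov: np.ndarray                # 2x2 covariance of (beta1, beta2)
    aicc_best: float
    aicc_null: float
    delta_aicc: float              # AICc_null - AICc_best (can be <= 0)
    n: int
    center: float                  # grand mean subtracted from the aggregate
    p_value: float | None = None
    table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def has_signal(self) -> bool:
        """Convenience: randomization p below 0.05 (call after the test)."""
        return self.p_value is not None and self.p_value < 0.05


# ---------------------------------------------------------------------------
# scan context: everything precomputed once per (species, variable)


@dataclass
class _ScanContext:
    y: np.ndarray                  # condition, n rows
    X0: np.ndarray                 # baseline design incl. intercept
    Q0: np.ndarray                 # thin QR factor of X0
    row_sy: np.ndarray             # row -> index into the site-year grid
    prefix: np.ndarray             # (n_sy, max_lag+1) prefix sums of daily values
    sy_site: np.ndarray            # site index per grid entry
    sy_year: np.ndarray            # year per grid entry
    years: np.ndarray              # distinct years in the grid
    candidates: list[tuple[int, int]]
    groups: np.ndarray             # individual ids (for the mixed engine)
    method: str                    # "ols" or "mixed"
    max_lag: int


def _series_map(climate, variable: str | None = None) -> dict[str, pd.Series]:
    """Normalize climate input to {station: date-indexed daily Series}."""
    if isinstance(climate, dict):
        return {k: v.sort_index() for k, v in climate.items()}
    df = climate
    if variable is not None and "variable" in df.columns:
        df = df[df["variable"] == variable]
        if df.empty:
            raise ValueError(f"no climate rows for variable {variable!r}")
    out = {}
    for st, grp in df.groupby("station"):
        out[str(st)] = pd.Series(
            grp["value"].to_numpy(), index=pd.DatetimeIndex(grp["date"])
        ).sort_index()
    return out


def _build_context(
    condition: pd.DataFrame,
    climate,
    variable: str | None = None,
    site_to_station: dict[str, str] | None = None,
    candidates: list[tuple[int, int]] | None = None,
    max_lag: int = 365,
    stride: int = 1,
    baseline: str = DEFAULT_BASELINE,
    method: str = "auto",
) -> _ScanContext:
    sort_cols = [c for c in ("site", "date", "year", "individual") if c in condition.columns]
    cond = condition.sort_values(sort_cols, kind="stable").reset_index(drop=True)
    if "year" not in cond.columns:
        cond = cond.assign(year=pd.DatetimeIndex(cond["date"]).year)
    years = np.sort(cond["year"].unique())
    if len(years) < 2:
        raise ValueError("need >= 2 distinct years for a window scan")
    sites = np.sort(cond["site"].unique())
    series = _series_map(climate, variable)
    if site_to_station is None:
        if len(series) != 1:
            raise ValueError("site_to_station required with multiple stations")
        only = next(iter(series))
        site_to_station = {s: only for s in sites}

    candidates = candidates or enumerate_windows(max_lag, stride)
    max_lag = max(w[0] for w in candidates)

    # site-year grid: all sites x all years, so year permutations stay on-grid
    n_sites, n_years = len(sites), len(years)
    site_idx = {s: i for i, s in enumerate(sites)}
    year_idx = {y: i for i, y in enumerate(years)}
    prefix = np.zeros((n_sites * n_years, max_lag + 1))
    sy_site = np.repeat(np.arange(n_sites), n_years)
    sy_year = np.tile(years, n_sites)
    for si, s in enumerate(sites):
        st = site_to_station[s]
        if st not in series:
            raise ValueError(f"no climate series for station {st!r} (site {s!r})")
        sr = series[st]
        for yi, y in enumerate(years):
            ref = pd.Timestamp(reference_date(int(y)))
            days = pd.date_range(ref - pd.Timedelta(days=max_lag), ref - pd.Timedelta(days=1))
            vals = sr.reindex(days)
            if vals.isna().any():
                gap = vals.index[vals.isna().to_numpy()][0].date()
                raise ValueError(
                    f"missing climate on {gap} (station {st}, reference {ref.date()})"
                )
            # vals[0] is offset max_lag .. vals[-1] is offset 1; store by offset
            daily = vals.to_numpy()[::-1]  # index k-1 = offset k
            prefix[si * n_years + yi, 1:] = np.cumsum(daily)

    row_sy = (
        cond["site"].map(site_idx).to_numpy() * n_years
        + cond["year"].map(year_idx).to_numpy()
    )
    X0 = np.asarray(patsy.dmatrix(baseline, cond, return_type="dataframe"))
    y = cond["condition"].to_numpy(float)
    Q0, _ = np.linalg.qr(X0)
    groups = cond["individual"].to_numpy() if "individual" in cond else np.arange(len(y))
    if method == "auto":
        recaptured = len(np.unique(groups)) < len(groups)
        method = "mixed" if recaptured else "ols"
    return _ScanContext(
        y=y,
        X0=X0,
        Q0=Q0,
        row_sy=row_sy,
        prefix=prefix,
        sy_site=sy_site,
        sy_year=sy_year,
        years=years,
        candidates=list(candidates),
        groups=groups,
        method=method,
        max_lag=max_lag,
    )


def _aggregates(ctx: _ScanContext, year_perm: np.ndarray | None = None) -> np.ndarray:
    """(n_sy, n_windows) window means; optionally with years remapped."""
    starts = np.array([w[0] for w in ctx.candidates])
    ends = np.array([w[1] for w in ctx.candidates])
    P = ctx.prefix
    if year_perm is not None:
        n_years = len(ctx.years)
        # site-year grid index (si*n_years + yi) -> (si*n_years + perm[yi])
        perm_idx = (
            np.repeat(np.arange(len(P) // n_years), n_years) * n_years
            + np.tile(year_perm, len(P) // n_years)
        )
        P = P[perm_idx]
    return (P[:, starts] - P[:, ends - 1]) / (starts - ends + 1)


def _scan_ols(ctx: _ScanContext, A: np.ndarray) -> dict:
    """Vectorized OLS over all candidate windows (Frisch-Waugh).

    A: per-site-year window means. Returns per-window AICc for the linear
    and quadratic shapes plus the selected model's details.
    """
    y, X0, Q0 = ctx.y, ctx.X0, ctx.Q0
    n, p0 = X0.shape
    Ac = A - A.mean(axis=0)  # grand-mean centring, equal weight per site-year
    centers = A.mean(axis=0)
    C1 = Ac[ctx.row_sy]
    C2 = C1**2

    ey = y - Q0 @ (Q0.T @ y)
    yy = float(ey @ ey)
    E1 = C1 - Q0 @ (Q0.T @ C1)
    E2 = C2 - Q0 @ (Q0.T @ C2)

    a = np.einsum("ij,ij->j", E1, E1)
    b = np.einsum("ij,ij->j", E1, E2)
    d = np.einsum("ij,ij->j", E2, E2)
    r1 = ey @ E1
    r2 = ey @ E2

    # linear shape
    ok1 = a > _EPS * n
    b1_lin = np.where(ok1, r1 / np.where(ok1, a, 1.0), 0.0)
    rss_lin = np.where(ok1, yy - b1_lin * r1, yy)

    # quadratic shape
    det = a * d - b * b
    ok2 = (det > _EPS * n) & ok1
    safe = np.where(ok2, det, 1.0)
    b1_q = np.where(ok2, (d * r1 - b * r2) / safe, np.where(ok1, b1_lin, 0.0))
    b2_q = np.where(ok2, (a * r2 - b * r1) / safe, 0.0)
    rss_q = np.where(ok2, yy - b1_q * r1 - b2_q * r2, rss_lin)

    k_lin, k_quad = p0 + 2, p0 + 3  # slope(s) + residual variance
    ll_lin = -0.5 * n * (np.log(2 * np.pi * np.maximum(rss_lin, _EPS) / n) + 1)
    ll_q = -0.5 * n * (np.log(2 * np.pi * np.maximum(rss_q, _EPS) / n) + 1)
    aicc_lin = -2 * ll_lin + 2 * k_lin + 2 * k_lin * (k_lin + 1) / (n - k_lin - 1)
    aicc_quad = -2 * ll_q + 2 * k_quad + 2 * k_quad * (k_quad + 1) / (n - k_quad - 1)
    aicc_null = aicc(gaussian_loglik(yy, n), p0 + 1, n)

    # joint selection over (window, shape) with deterministic tie-breaks:
    # AICc, then duration, then recency (smaller end), then linear first
    starts = np.array([w[0] for w in ctx.candidates])
    ends = np.array([w[1] for w in ctx.candidates])
    durations = starts - ends + 1
    aicc_all = np.concatenate([aicc_lin, aicc_quad])
    dur_all = np.concatenate([durations, durations])
    end_all = np.concatenate([ends, ends])
    shp_all = np.concatenate([np.zeros(len(ends)), np.ones(len(ends))])
    best = np.lexsort((shp_all, end_all, dur_all, aicc_all))[0]
    wi = best % len(ctx.candidates)
    is_quad = best >= len(ctx.candidates)

    sigma2 = (rss_q[wi] if is_quad else rss_lin[wi]) / (n - p0 - (2 if is_quad else 1))
    if is_quad and ok2[wi]:
        Minv = (
            np.array([[d[wi], -b[wi]], [-b[wi], a[wi]]]) / (a[wi] * d[wi] - b[wi] ** 2)
        )
        cov = sigma2 * Minv
        beta1, beta2 = float(b1_q[wi]), float(b2_q[wi])
    else:
        cov = np.zeros((2, 2))
        cov[0, 0] = sigma2 / a[wi] if ok1[wi] else np.inf
        beta1, beta2 = float(b1_lin[wi]), 0.0

    return {
        "window": ctx.candidates[wi],
        "shape": "quadratic" if is_quad else "linear",
        "beta1": beta1,
        "beta2": beta2,
        "cov": cov,
        "aicc_best": float(aicc_all[best]),
        "aicc_null": float(aicc_null),
        "center": float(centers[wi]),
        "aicc_lin": aicc_lin,
        "aicc_quad": aicc_quad,
    }


def _scan_mixed(ctx: _ScanContext, A: np.ndarray) -> dict:
    """Per-candidate mixed-model scan (individual random intercept, ML)."""
    from statsmodels.regression.mixed_linear_model import MixedLM

    y, X0 = ctx.y, ctx.X0
    n, p0 = X0.shape
    Ac = A - A.mean(axis=0)
    centers = A.mean(axis=0)

    def _fit(X, k):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = MixedLM(y, X, groups=ctx.groups).fit(reml=False)
        if not np.isfinite(fit.llf):
            raise RuntimeError("non-finite likelihood")
        return fit, aicc(float(fit.llf), k, n)

    _, aicc_null = _fit(X0, p0 + 2)  # + random-intercept var + residual var
    rows = []
    fits = {}
    for wi, w in enumerate(ctx.candidates):
        c1 = Ac[ctx.row_sy, wi]
        for shape, cols, k in (
            ("linear", [c1], p0 + 3),
            ("quadratic", [c1, c1**2], p0 + 4),
        ):
            try:
                fit, a_val = _fit(np.column_stack([X0] + cols), k)
            except Exception as exc:  # non-convergence: skip candidate shape
                logger.warning("skipping window %s (%s): %s", w, shape, exc)
                continue
            fits[(wi, shape)] = fit
            rows.append(
                {
                    "wi": wi,
                    "shape": shape,
                    "aicc": a_val,
                    "duration": w[0] - w[1] + 1,
                    "end": w[1],
                }
            )
    if not rows:
        raise RuntimeError("every candidate window failed to fit")
    tab = pd.DataFrame(rows).sort_values(
        ["aicc", "duration", "end", "shape"], kind="stable"
    )
    top = tab.iloc[0]
    wi, shape = int(top["wi"]), str(top["shape"])
    fit = fits[(wi, shape)]
    params = np.asarray(fit.fe_params)
    cov_fe = np.asarray(fit.cov_params())[: len(params), : len(params)]
    if shape == "quadratic":
        beta1, beta2 = float(params[-2]), float(params[-1])
        cov = cov_fe[-2:, -2:]
    else:
        beta1, beta2 = float(params[-1]), 0.0
        cov = np.zeros((2, 2))
        cov[0, 0] = cov_fe[-1, -1]
    lin = tab[tab["shape"] == "linear"].set_index("wi")["aicc"]
    quad = tab[tab["shape"] == "quadratic"].set_index("wi")["aicc"]
    return {
        "window": ctx.candidates[wi],
        "shape": shape,
        "beta1": beta1,
        "beta2": beta2,
        "cov": cov,
        "aicc_best": float(top["aicc"]),
        "aicc_null": float(aicc_null),
        "center": float(centers[wi]),
        "aicc_lin": lin.reindex(range(len(ctx.candidates))).to_numpy(),
        "aicc_quad": quad.reindex(range(len(ctx.candidates))).to_numpy(),
    }


def _scan(ctx: _ScanContext, year_perm: np.ndarray | None = None) -> dict:
    A = _aggregates(ctx, year_perm)
    return _scan_ols(ctx, A) if ctx.method == "ols" else _scan_mixed(ctx, A)


def scan_variable(
    condition: pd.DataFrame,
    climate,
    variable: str | None = None,
    site_to_station: dict[str, str] | None = None,
    candidates: list[tuple[int, int]] | None = None,
    max_lag: int = 365,
    stride: int = 1,
    baseline: str = DEFAULT_BASELINE,
    method: str = "auto",
    keep_table: bool = True,
) -> WindowScanResult:
    """Scan all candidate windows for one species x one climate variable.

    ``condition`` is a per-capture table with columns condition, site, date
    (or year), individual and the baseline covariates; ``climate`` is either
    a long table (station, variable, date, value) or a {station: Series}
    mapping. ``method`` is "ols", "mixed" or "auto" (mixed only when some
    individual was recaptured).
    """
    ctx = _build_context(
        condition, climate, variable, site_to_station, candidates, max_lag, stride,
        baseline, method,
    )
    res = _scan(ctx)
    table = None
    if keep_table:
        table = pd.DataFrame(
            {
                "start": [w[0] for w in ctx.candidates],
                "end": [w[1] for w in ctx.candidates],
                "aicc_linear": res["aicc_lin"],
                "aicc_quadratic": res["aicc_quad"],
            }
        )
    return WindowScanResult(
        window=res["window"],
        shape=res["shape"],
        beta1=res["beta1"],
        beta2=res["beta2"],
        cov=res["cov"],
        aicc_best=res["aicc_best"],
        aicc_null=res["aicc_null"],
        delta_aicc=res["aicc_null"] - res["aicc_best"],
        n=len(ctx.y),
        center=res["center"],
        table=table,
    )


def randomization_test(
    condition: pd.DataFrame,
    climate,
    variable: str | None = None,
    site_to_station: dict[str, str] | None = None,
    n_rand: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    **scan_kwargs,
) -> WindowScanResult:
    """Scan plus a year-permutation test of the best window's improvement.

    The year -> climate mapping is permuted ``n_rand`` times (condition data
    untouched, seasonal covariates preserved), the full scan re-run each
    time, and

        p = (1 + #{permuted best dAICc >= observed best dAICc}) / (n_rand + 1).

    The variable "has a signal" when p < alpha. Requires >= 3 distinct years
    and n_rand >= 19.
    """
    if n_rand < 19:
        raise ValueError("n_rand must be >= 19")
    ctx = _build_context(condition, climate, variable, site_to_station, **scan_kwargs)
    if len(ctx.years) < 3:
        raise ValueError("need >= 3 distinct years for the year-permutation test")
    obs = _scan(ctx)
    obs_delta = obs["aicc_null"] - obs["aicc_best"]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 600]))
    n_years = len(ctx.years)
    count = 0
    for _ in range(n_rand):
        perm = rng.permutation(n_years)
        r = _scan(ctx, year_perm=perm)
        if (r["aicc_null"] - r["aicc_best"]) >= obs_delta:
            count += 1
    p = (1 + count) / (n_rand + 1)
    logger.info(
        "randomization: window=%s dAICc=%.2f p=%.3f (n_rand=%d)",
        obs["window"], obs_delta, p, n_rand,
    )
    return WindowScanResult(
        window=obs["window"],
        shape=obs["shape"],
        beta1=obs["beta1"],
        beta2=obs["beta2"],
        cov=obs["cov"],
        aicc_best=obs["aicc_best"],
        aicc_null=obs["aicc_null"],
        delta_aicc=obs_delta,
        n=len(ctx.y),
        center=obs["center"],
        p_value=p,
    )
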