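"""Weighted one-way random-intercept linear mixed model (REML/ML).

Model:  y_i = x_i' beta + a_{g(i)} + e_i,   a_g ~ N(0, s2_group),
        e_i ~ N(0, s2_resid / w_i)

with known positive observation weights w_i. This is the engine behind the
species-signal variance decomposition (intercept-only, weights = inverse
standard error of site-level sensitivity estimates, species as the group)
and the site-level trait models (trait fixed effect, species random
intercept).

The likelihood is profiled: for a given variance ratio theta =
s2_group / s2_resid the GLS solution and the residual variance have closed
forms via Sherman-Morrison on each group's covariance block, leaving a
one-dimensional optimization over theta >= 0 (the boundary theta = 0, i.e.
a zero group variance, is checked explicitly, so negative variance
components are clamped at zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar


@dataclass
class MixedFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_group: float
    sigma2_resid: float
    theta: float
    llf: float                 # log-likelihood at the optimum (REML or ML)
    method: str
    n: int
    p: int
    converged: bool = True

    @property
    def icc(self) -> float:
        tot = self.sigma2_group + self.sigma2_resid
        return self.sigma2_group / tot if tot > 0 else 0.0

    def loglik_ml(self) -> float:
        if self.method == "ml":
            return self.llf
        raise ValueError("fit with method='ml' for an ML log-likelihood")


def _profile(theta: float, y, X, group_slices, w):
    """Profiled quantities at a given variance ratio theta.

    Returns (A, b, yy, logdetV0) where A = X'V0^-1 X, b = X'V0^-1 y,
    yy = y'V0^-1 y and V0 = diag(1/w) + theta * block(11').
    """
    p = X.shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    yy = 0.0
    logdet = 0.0
    for sl in group_slices:
        wg = w[sl]
        Xg = X[sl]
        yg = y[sl]
        t = wg.sum()
        c = theta / (1.0 + theta * t)
        Xw = Xg * wg[:, None]
        yw = yg * wg
        sx = Xw.sum(axis=0)
        sy = yw.sum()
        A += Xg.T @ Xw - c * np.outer(sx, sx)
        b += Xg.T @ yw - c * sx * sy
        yy += yg @ yw - c * sy * sy
        logdet += -np.log(wg).sum() + np.log1p(theta * t)
    return A, b, yy, logdet


def fit_weighted_random_intercept(
    y,
    X,
    groups,
    weights=None,
    method: str = "reml",
) -> MixedFit:
    """Fit the weighted random-intercept model by REML (default) or ML."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    # normalize to mean 1: a pure reparameterization (sigma2_resid absorbs the
    # constant) that makes sigma2_resid the average per-observation residual
    # variance, so variance ratios are invariant to rescaling the weights
    w = w / w.mean()
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")

    groups = np.asarray(groups)
    order = np.argsort(groups, kind="stable")
    y, X, w, groups = y[order], X[order], w[order], groups[order]
    _, starts = np.unique(groups, return_index=True)
    bounds = np.append(starts, n)
    group_slices = [slice(bounds[i], bounds[i + 1]) for i in range(len(starts))]

    dof = n - p if method == "reml" else n

    def negll(log_theta: float) -> float:
        return -_loglik(np.exp(log_theta))

    def _loglik(theta: float) -> float:
        A, b, yy, logdet = _profile(theta, y, X, group_slices, w)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return -np.inf
        q = yy - beta @ b
        if q <= 0:
            q = np.finfo(float).tiny
        s2 = q / dof
        ll = -0.5 * (dof * (np.log(2 * np.pi * s2) + 1.0) + logdet)
        if method == "reml":
            # profiled REML: (n-p) log s2 + log|V0| + log|X'V0^-1 X|
            sign, logdetA = np.linalg.slogdet(A)
            if sign <= 0:
                return -np.inf
            ll -= 0.5 * logdetA
        return ll

    res = minimize_scalar(negll, bounds=(-14.0, 14.0), method="bounded",
                          options={"xatol": 1e-10})
    candidates = [(0.0, _loglik(0.0)), (float(np.exp(res.x)), -res.fun)]
    theta, llf = max(candidates, key=lambda t: t[1])
    if not np.isfinite(llf):
        raise RuntimeError(f"variance-component optimization failed: {res}")

    A, b, yy, _ = _profile(theta, y, X, group_slices, w)
    beta = np.linalg.solve(A, b)
    q = max(yy - beta @ b, np.finfo(float).tiny)
    s2_resid = q / dof
    return MixedFit(
        beta=beta,
        cov_beta=s2_resid * np.linalg.inv(A),
        sigma2_group=theta * s2_resid,
        sigma2_resid=s2_resid,
        theta=theta,
        llf=float(llf),
        method=method,
        n=n,
        p=p,
        converged=bool(res.success),
    )


def anova_variance_components(values: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Closed-form one-way ANOVA variance components for a balanced design.

    sigma2_within = MSW; sigma2_between = (MSB - MSW) / n_per_group
    (clamped at zero). Used as an independent oracle for the REML fit.
    """
    df = pd.DataFrame({"y": values, "g": groups})
    counts = df.groupby("g").size()
    if counts.nunique() != 1:
        raise ValueError("ANOVA oracle requires a balanced design")
    m = counts.iloc[0]
    k = len(counts)
    grand = df["y"].mean()
    means = df.groupby("g")["y"].mean()
    msb = m * ((means - grand) ** 2).sum() / (k - 1)
    msw = ((df["y"] - df["g"].map(means)) ** 2).sum() / (k * (m - 1))
    return max((msb - msw) / m, 0.0), msw
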