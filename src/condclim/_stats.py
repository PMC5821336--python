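"""Small shared statistical helpers: AICc, Gaussian log-likelihood, Akaike weights."""

from __future__ import annotations

import numpy as np

__all__ = ["aicc", "gaussian_loglik", "akaike_weights"]


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion.

    AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1).

    Parameters
    ----------
    loglik : maximized log-likelihood of the model.
    k : number of estimated parameters (including the residual variance
        for Gaussian models).
    n : number of observations.
    """
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n <= k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def gaussian_loglik(rss: float, n: int) -> float:
    """Maximized Gaussian log-likelihood given a residual sum of squares.

    Uses the ML variance estimate sigma^2 = rss / n.
    """
    if rss <= 0:
        # numerically perfect fit; bound sigma^2 away from zero
        rss = np.finfo(float).tiny
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def akaike_weights(aicc_values: np.ndarray) -> np.ndarray:
    """Akaike weights w_m = exp(-delta_m / 2) / sum_j exp(-delta_j / 2)."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()
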