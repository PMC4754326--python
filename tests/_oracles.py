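"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

import numpy as np


def nipals_pls1_fitted(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """Training-set fitted values of an A-component NIPALS PLS1 regression.

    Classical deflation algorithm for a single response: at each step the
    weight is the covariance direction of the current residuals, both X
    and y are deflated by the extracted component. Written independently
    of the package's OPLS code path.
    """
    X = np.asarray(X, dtype=float).copy()
    y = np.asarray(y, dtype=float).ravel()
    y_mean = y.mean()
    ya = y - y_mean
    fitted = np.full(y.shape, y_mean)
    for _ in range(n_components):
        w = X.T @ ya
        w = w / np.linalg.norm(w)
        t = X @ w
        tt = float(t @ t)
        q = float(ya @ t) / tt
        p = X.T @ t / tt
        X = X - np.outer(t, p)
        ya = ya - q * t
        fitted = fitted + q * t
    return fitted


def ols_slope_and_se(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple-regression slope and its standard error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ (y - y.mean())) / sxx
    resid = y - y.mean() - slope * xc
    dof = len(x) - 2
    se = np.sqrt(float(resid @ resid) / dof / sxx)
    return slope, se


def two_sample_mean_diff_se(sd: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Closed-form SE of a difference of two independent sample means."""
    sd = np.asarray(sd, dtype=float)
    return sd * np.sqrt(1.0 / n1 + 1.0 / n2)
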