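"""Independent brute-force oracles used only by the test suite.

These deliberately share no code path with the package: the restricted
log-likelihood is re-derived here and maximized by exhaustive grid search,
and weighted least squares is recomputed from the normal equations.
"""

import numpy as np


def restricted_ll_grid(y, v, t2_grid, X=None):
    """Restricted log-likelihood evaluated on a tau^2 grid (vectorized for
    the intercept-only model, looped for a general design)."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    t2 = np.asarray(t2_grid, float)
    if X is None:
        w = 1.0 / (v[:, None] + t2[None, :])  # k x G
        sw = w.sum(axis=0)
        mu = (w * y[:, None]).sum(axis=0) / sw
        ll = -0.5 * (
            np.log(v[:, None] + t2[None, :]).sum(axis=0)
            + np.log(sw)
            + (w * (y[:, None] - mu[None, :]) ** 2).sum(axis=0)
        )
        return ll
    X = np.asarray(X, float)
    out = np.empty(t2.size)
    for g, t in enumerate(t2):
        w = 1.0 / (v + t)
        a = (X.T * w) @ X
        beta = np.linalg.solve(a, (X.T * w) @ y)
        r = y - X @ beta
        out[g] = -0.5 * (np.sum(np.log(v + t)) + np.linalg.slogdet(a)[1] + np.sum(w * r * r))
    return out


def grid_reml_tau2(y, v, X=None, upper=10.0, step=1e-4):
    """Grid-search REML tau^2 (the stated oracle: 1e-4 step over [0, upper])."""
    grid = np.arange(0.0, upper + step, step)
    ll = restricted_ll_grid(y, v, grid, X)
    return float(grid[int(np.argmax(ll))])


def wls_fit(y, v, X, tau2):
    """Weighted least squares at a fixed tau^2, straight from the normal
    equations: beta = (X'WX)^-1 X'Wy, cov = (X'WX)^-1."""
    y = np.asarray(y, float)
    w = 1.0 / (np.asarray(v, float) + tau2)
    a = (X.T * w) @ X
    beta = np.linalg.solve(a, (X.T * w) @ y)
    return beta, np.linalg.inv(a)


def tau2_dl(y, v):
    """DerSimonian-Laird moment estimator, independent re-derivation."""
    y = np.asarray(y, float)
    w = 1.0 / np.asarray(v, float)
    mu = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - mu) ** 2)
    return max(0.0, (q - (y.size - 1)) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
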