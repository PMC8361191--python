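"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's own code paths: Spearman via
scipy.stats.spearmanr, OLS via statsmodels, and a dense (no block
factorization) restricted-likelihood maximization for the
variance-components model.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.stats import spearmanr


def coupling_oracle(sc, fc, partner_masks):
    """Row-wise Spearman over explicit partner sets, via scipy.stats.spearmanr."""
    n = sc.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        mask = partner_masks[i].copy()
        mask[i] = False
        if mask.sum() < 3:
            continue
        x, y = sc[i, mask], fc[i, mask]
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            continue
        out[i] = spearmanr(x, y).statistic
    return out


def dense_restricted_loglik(sigma2, y, X, K, L, T):
    """Restricted log-likelihood evaluated with explicit dense matrices."""
    n = y.size
    V = (
        sigma2[0] * T @ K @ T.T
        + sigma2[1] * T @ L @ T.T
        + sigma2[2] * T @ T.T
        + sigma2[3] * np.eye(n)
    )
    sign, logdet_v = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    xtvix = X.T @ Vi @ X
    s2, logdet_x = np.linalg.slogdet(xtvix)
    if s2 <= 0:
        return -np.inf
    beta = np.linalg.solve(xtvix, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (logdet_v + logdet_x + r @ Vi @ y)


def dense_reml_oracle(y, X, K, L, T, starts=None):
    """Maximize the dense restricted likelihood; returns (sigma2, loglik)."""
    vy = y.var(ddof=1)
    if starts is None:
        starts = [
            np.full(4, vy / 4),
            np.array([0.7, 0.1, 0.1, 0.1]) * vy,
            np.array([0.1, 0.1, 0.1, 0.7]) * vy,
        ]
    best = None
    for s0 in starts:
        res = minimize(
            lambda u: -dense_restricted_loglik(np.exp(u), y, X, K, L, T),
            np.log(np.maximum(s0, 1e-8)),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 8000,
                     "maxfev": 8000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return np.exp(best.x), -best.fun
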