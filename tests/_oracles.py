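"""Independent brute-force oracles used to cross-check the implementation."""

import numpy as np
from scipy import stats


def ols_oracle(y, X):
    """OLS with intercept by explicit normal equations.

    Returns (coefficients excl. intercept, two-sided t p-values excl.
    intercept, unadjusted R^2).  Deliberately written from the textbook
    formulas, independent of the fitting path under test.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n = y.shape[0]
    A = np.column_stack([np.ones(n), X])
    k = A.shape[1]
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ beta
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    return beta[1:], p[1:], r2


def delta_method_mean_ratio(mu_num, sd_num, mu_den, sd_den):
    """Second-order Taylor expansion of E[N/D] for independent N, D.

    E[N/D] ~= (mu_N / mu_D) * (1 + sd_D^2 / mu_D^2).
    """
    return (mu_num / mu_den) * (1.0 + sd_den**2 / mu_den**2)
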