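"""Independent brute-force oracles used only by the tests.

The logistic-likelihood oracle is a cyclic coordinate grid search at a fixed
1e-3 step: for each coefficient in turn it scans an exhaustive 1-D grid of
candidate values (all others held fixed) and keeps the grid maximizer,
sweeping until no coefficient moves.  The binomial log-likelihood is jointly
concave, so the sweeps converge to the global maximum to within the grid
step.  It shares no code with the fitting path under test.
"""

import numpy as np


def logit_loglik(beta, y, X):
    q = X @ beta
    return float(np.sum(y * q - np.logaddexp(0.0, q)))


def grid_ml_logit(y, X, lo=-8.0, hi=8.0, step=1e-3, max_sweeps=100):
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    p = X.shape[1]
    beta = np.zeros(p)
    grid = np.arange(lo, hi + step / 2, step)
    for _ in range(max_sweeps):
        prev = beta.copy()
        for j in range(p):
            base = X @ beta - X[:, j] * beta[j]
            q = base[:, None] + np.outer(X[:, j], grid)
            ll = np.sum(y[:, None] * q - np.logaddexp(0.0, q), axis=0)
            beta[j] = grid[int(np.argmax(ll))]
        if np.max(np.abs(beta - prev)) < step / 2:
            break
    return beta


def wilson_interval_brute(k, n, alpha=0.05, tol=1e-6):
    """Score interval by bisection on the score test statistic: the set of p
    with |phat - p| <= z * sqrt(p(1-p)/n)."""
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    phat = k / n

    def inside(p):
        if p <= 0.0:
            return k == 0
        if p >= 1.0:
            return k == n
        return abs(phat - p) <= z * np.sqrt(p * (1 - p) / n) + 1e-15

    def bisect(lo_out, hi_in):
        # lo_out outside the set, hi_in inside; find the boundary
        lo, hi = lo_out, hi_in
        while abs(hi - lo) > tol:
            mid = 0.5 * (lo + hi)
            if inside(mid):
                hi = mid
            else:
                lo = mid
        return hi

    lower = 0.0 if inside(0.0) else bisect(0.0, phat if phat > 0 else 1e-12)
    if inside(1.0):
        upper = 1.0
    else:
        lo, hi = phat, 1.0
        while abs(hi - lo) > tol:
            mid = 0.5 * (lo + hi)
            if inside(mid):
                lo = mid
            else:
                hi = mid
        upper = lo
    return lower, upper
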