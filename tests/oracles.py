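"""Independent oracles used by the acceptance tests.

Everything here is written against the model definition directly (slogdet /
explicit inverses / iterated dense grid search) and shares no code with the
package's AI-REML path, so it can certify the implementation's likelihood
values and optima.
"""

import itertools

import numpy as np
from scipy import optimize

# canonical parameter order: s2_a0, s_a01, s2_a1, s2_t0, s_t01, s2_t1
_INTERCEPT_PARAMS = (0, 3)


def restricted_loglik(theta6, y, K, c):
    """REML log-likelihood -(log|V| + log|1'V^-1 1| + y'Py)/2 evaluated from
    the covariance definition, independent of the package implementation."""
    theta6 = np.asarray(theta6, dtype=float)
    V = K * (
        theta6[0]
        + theta6[1] * (c[:, None] + c[None, :])
        + theta6[2] * np.outer(c, c)
    )
    V = V + np.diag(theta6[3] + 2 * theta6[4] * c + theta6[5] * c**2)
    w = np.linalg.eigvalsh(V)
    if w[0] <= 0:
        return -np.inf
    Vinv = np.linalg.inv(V)
    logdetV = float(np.sum(np.log(w)))
    ones = np.ones_like(y)
    xtvix = float(ones @ Vinv @ ones)
    if xtvix <= 0:
        return -np.inf
    beta = float(ones @ Vinv @ y) / xtvix
    r = y - beta
    return float(-0.5 * (logdetV + np.log(xtvix) + r @ Vinv @ r))


def _psd_ok(t):
    return (
        t[0] >= 0 and t[2] >= 0 and t[0] * t[2] - t[1] ** 2 >= -1e-12
        and t[3] >= 0 and t[5] >= 0 and t[3] * t[5] - t[4] ** 2 >= -1e-12
    )


def _coordinate_polish(x, free_idx, y, K, c, vp, n_passes=30):
    """Refine a grid optimum by bounded line searches, one parameter at a
    time, staying inside the PSD region."""
    x = x.copy()

    def value(xx):
        t = np.zeros(6)
        t[free_idx] = xx
        if not _psd_ok(t):
            return -np.inf
        return restricted_loglik(t, y, K, c)

    current = value(x)
    for _ in range(n_passes):
        improved = False
        for d in range(len(free_idx)):

            def neg(z):
                xx = x.copy()
                xx[d] = z
                v = value(xx)
                return 1e10 if not np.isfinite(v) else -v

            res = optimize.minimize_scalar(
                neg, bounds=(x[d] - 0.5 * vp, x[d] + 0.5 * vp),
                method="bounded", options=dict(xatol=1e-10),
            )
            if -res.fun > current + 1e-12:
                x[d] = res.x
                current = -res.fun
                improved = True
        if not improved:
            break
    return current


def grid_search_max(y, K, c, free_idx, n_points=5, n_rounds=9):
    """Iterated dense grid search for the constrained REML maximum.

    The grid covers a box around plausible values, shrinks around the best
    point each round, and is restricted to the PSD parameter region; a final
    coordinate polish tightens the certificate.
    """
    free_idx = np.asarray(free_idx)
    k = len(free_idx)
    vp = float(np.var(y, ddof=1))
    centers = np.array(
        [0.5 * vp if i in _INTERCEPT_PARAMS else 0.0 for i in free_idx]
    )
    half = np.array([1.0 * vp if i in _INTERCEPT_PARAMS else 0.6 * vp
                     for i in free_idx])
    best_ll, best_x = -np.inf, centers.copy()
    for _ in range(n_rounds):
        axes = [
            np.linspace(centers[d] - half[d], centers[d] + half[d], n_points)
            for d in range(k)
        ]
        for combo in itertools.product(*axes):
            t = np.zeros(6)
            t[free_idx] = combo
            if not _psd_ok(t):
                continue
            ll = restricted_loglik(t, y, K, c)
            if ll > best_ll:
                best_ll, best_x = ll, np.array(combo)
        centers = best_x.copy()
        half = half * (2.0 / (n_points - 1))
    return _coordinate_polish(best_x, free_idx, y, K, c, vp)
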