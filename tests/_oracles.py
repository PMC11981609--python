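"""Independent oracles used only by the test suite.

These deliberately avoid the package's Laplace code path: the marginal
likelihood is evaluated by adaptive Gauss-Hermite quadrature built from
first principles, degenerate limits use closed forms or statsmodels'
fixed-effect NB GLM, and BH is re-derived by direct enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special


def nb_logpmf(y, mu, theta):
    return (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def aghq_marginal_loglik(data, params, n_nodes: int = 64) -> float:
    """AGHQ marginal log-likelihood of the position model.

    ``data`` is a PositionDataset; ``params`` the package's parameter vector
    [beta_cond, beta_var flattened, log sigma, log theta]. Each barcode's
    scalar random effect is integrated with Gauss-Hermite nodes recentered
    at the per-barcode penalized mode found by dense grid + refinement
    (independent of the package's Newton solver).
    """
    C, V = data.n_conditions, data.n_variants
    beta_c = params[:C]
    beta_v = params[C : C + V * C].reshape(V, C)
    sigma2 = np.exp(2 * params[-2])
    theta = np.exp(params[-1])

    nodes, weights = special.roots_hermite(n_nodes)
    total = 0.0
    for k in range(data.n_barcodes):
        cells = data.barcode_idx == k
        y = data.y[cells]
        cond = data.cond_idx[cells]
        var = data.var_idx[cells]
        eta = beta_c[cond] + data.offset[cells]
        eta = eta + np.where(var >= 0, beta_v[np.maximum(var, 0), cond], 0.0)

        def neg_h(a):
            mu = np.exp(eta + a)
            return -(
                nb_logpmf(y, mu, theta).sum()
                - a**2 / (2 * sigma2)
                - 0.5 * np.log(2 * np.pi * sigma2)
            )

        res = optimize.minimize_scalar(neg_h, bounds=(-20, 20), method="bounded",
                                       options={"xatol": 1e-10})
        mode = res.x
        # curvature at the mode, by central differences
        eps = 1e-4
        hpp = (neg_h(mode + eps) - 2 * neg_h(mode) + neg_h(mode - eps)) / eps**2
        s = 1.0 / np.sqrt(max(hpp, 1e-12))
        z = mode + np.sqrt(2.0) * s * nodes
        h_vals = np.array([-neg_h(a) for a in z])
        log_terms = np.log(weights) + nodes**2 + h_vals
        m = log_terms.max()
        total += m + np.log(np.sum(np.exp(log_terms - m))) + np.log(np.sqrt(2.0) * s)
    return float(total)


def aghq_fit(data, start, bounds, n_nodes: int = 64):
    """Maximize the AGHQ likelihood directly (numerical gradients)."""
    res = optimize.minimize(
        lambda p: -aghq_marginal_loglik(data, p, n_nodes),
        start,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 300, "ftol": 1e-12},
    )
    return res


def fixed_effect_nb_fit(data):
    """statsmodels NB2 GLM oracle for the sigma = 0 limit.

    Returns (beta_cond, beta_var, theta_hat) on the natural-log scale with
    the same reference coding as the package.
    """
    import statsmodels.api as sm

    C, V = data.n_conditions, data.n_variants
    n = data.y.size
    X = np.zeros((n, C + V * C))
    for c in range(C):
        X[data.cond_idx == c, c] = 1.0
    mask = data.var_idx >= 0
    flat = data.var_idx[mask] * C + data.cond_idx[mask]
    X[np.flatnonzero(mask), C + flat] = 1.0
    model = sm.NegativeBinomial(data.y, X, offset=data.offset)
    res = model.fit(disp=0, maxiter=200)
    beta = res.params[: C + V * C]
    theta = 1.0 / res.params[-1]  # statsmodels alpha = 1/theta
    return beta[:C], beta[C:].reshape(V, C), theta


def bh_reference(pvals):
    """Textbook BH step-up by direct enumeration."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def ols_line(x, y):
    """Plain least-squares slope/intercept."""
    b, a = np.polyfit(x, y, 1)
    return a, b
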