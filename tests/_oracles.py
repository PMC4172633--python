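"""Independent oracles used by the test suite.

Everything here is deliberately written against the *definitions* of the
quantities under test, not against the package's implementation paths:
an adaptive Gauss-Hermite-quadrature maximum-likelihood fit for the
single-factor binomial mixed model, and classical method-of-moments
variance components for the balanced one-way Gaussian layout.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special


def _group_mode(xb_g, y_g, sigma, tol=1e-10):
    """Mode and curvature of the per-group integrand over the standard
    normal random effect u."""
    u = 0.0
    for _ in range(100):
        eta = xb_g + sigma * u
        mu = special.expit(eta)
        g = sigma * np.sum(y_g - mu) - u
        h = -(sigma ** 2) * np.sum(mu * (1 - mu)) - 1.0
        step = -g / h
        u += step
        if abs(g) < tol:
            break
    eta = xb_g + sigma * u
    mu = special.expit(eta)
    curv = (sigma ** 2) * np.sum(mu * (1 - mu)) + 1.0
    return u, 1.0 / np.sqrt(curv)


def aghq_binomial_loglik(beta, sigma, X, y, groups, n_nodes=31):
    """Marginal log-likelihood of a one-random-intercept logistic model by
    adaptive Gauss-Hermite quadrature."""
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    xb = X @ beta
    total = 0.0
    for g in np.unique(groups):
        sel = groups == g
        xb_g, y_g = xb[sel], y[sel]
        uhat, tau = _group_mode(xb_g, y_g, sigma)

        def logf(u):
            eta = xb_g + sigma * u
            return float(y_g @ eta - np.logaddexp(0.0, eta).sum()
                         - 0.5 * u * u)

        u_j = uhat + np.sqrt(2.0) * tau * nodes
        vals = np.array([logf(u) for u in u_j]) + nodes ** 2
        m = vals.max()
        integral = np.sqrt(2.0) * tau * np.sum(weights * np.exp(vals - m))
        total += m + np.log(integral) - 0.5 * np.log(2.0 * np.pi)
    return total


def aghq_binomial_mle(X, y, groups, n_nodes=31):
    """Maximise the quadrature likelihood over (beta, log sigma)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]

    def nll(params):
        return -aghq_binomial_loglik(params[:p], np.exp(params[p]),
                                     X, y, groups, n_nodes)

    x0 = np.concatenate([np.zeros(p), [0.0]])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxiter": 5000})
    beta = res.x[:p]
    sigma = float(np.exp(res.x[p]))
    return beta, sigma, -res.fun


def balanced_anova_components(y, groups):
    """Method-of-moments variance components for a balanced one-way
    random-effects layout (classical expected-mean-squares estimators)."""
    y = np.asarray(y, dtype=float)
    levels = np.unique(groups)
    a = len(levels)
    counts = np.array([(groups == g).sum() for g in levels])
    if len(set(counts)) != 1:
        raise ValueError("layout is not balanced")
    n = counts[0]
    means = np.array([y[groups == g].mean() for g in levels])
    grand = y.mean()
    ssb = n * np.sum((means - grand) ** 2)
    ssw = sum(float(((y[groups == g] - means[i]) ** 2).sum())
              for i, g in enumerate(levels))
    msb = ssb / (a - 1)
    mse = ssw / (a * (n - 1))
    sigma_u2 = max(0.0, (msb - mse) / n)
    return sigma_u2, mse
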