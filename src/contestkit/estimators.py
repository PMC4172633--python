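"""Mixed-effects estimators with crossed random intercepts.

Two scikit-learn-style estimators implement the model families used
throughout the package:

* :class:`BinomialGLMM` — mixed-effects logistic regression whose marginal
  likelihood is maximised under the Laplace approximation to the
  random-effects integral.
* :class:`GaussianLMM` — linear mixed model estimated by REML (default) or
  maximum likelihood, with closed-form GLS fixed effects at each candidate
  variance configuration.

Both accept crossed random intercepts as an ``(n, k)`` integer matrix of
group codes passed to ``fit`` alongside ``X`` and ``y``: each column is an
independent grouping factor with its own variance component.  Fits are
deterministic: the outer optimisation is bounded quasi-Newton on the
log-standard-deviation scale from a fixed grid of starting points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

__all__ = [
    "BinomialGLMM",
    "GaussianLMM",
    "ConvergenceWarning",
    "SeparationWarning",
    "satterthwaite_df",
    "wald_f_test",
]

# log-SD box for the outer optimiser; the lower edge is numerically
# indistinguishable from a zero variance component.
_LOGSD_LO = -8.0
_LOGSD_HI = 5.0
_MULTISTART = (-4.0, -0.5, 0.7)  # fixed 3-point grid on log-SD


class ConvergenceWarning(UserWarning):
    pass


class SeparationWarning(UserWarning):
    pass


def _as_groups(groups, n):
    if groups is None:
        return np.empty((n, 0), dtype=np.intp), []
    g = np.asarray(groups)
    if g.ndim == 1:
        g = g[:, None]
    if g.shape[0] != n:
        raise ValueError(f"groups has {g.shape[0]} rows, expected {n}")
    codes = np.empty_like(g, dtype=np.intp)
    levels = []
    for j in range(g.shape[1]):
        lev, codes[:, j] = np.unique(g[:, j], return_inverse=True)
        levels.append(lev)
    return codes, levels


def _dense_Z(codes):
    """Indicator matrix for all factors, columns blocked per factor."""
    n, k = codes.shape
    sizes = [int(codes[:, j].max()) + 1 if n else 0 for j in range(k)]
    q = int(sum(sizes))
    Z = np.zeros((n, q))
    off = 0
    for j in range(k):
        Z[np.arange(n), off + codes[:, j]] = 1.0
        off += sizes[j]
    return Z, np.asarray(sizes, dtype=int)


def _add_intercept(X, fit_intercept):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if fit_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    return X


# --------------------------------------------------------------------------
# Binomial GLMM (Laplace)
# --------------------------------------------------------------------------

def _bernoulli_loglik(eta, y):
    # sum_i y*eta - log(1 + exp(eta)), stable
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _inner_mode(xb, y, Z, dinv, b0, tol=1e-9, max_iter=100):
    """Newton maximisation of the penalised Bernoulli log-likelihood over b.

    Returns (b_hat, cho_factor(H), penalised loglik at mode).
    """
    b = b0.copy()

    def pen_ll(b):
        eta = xb + Z @ b
        return _bernoulli_loglik(eta, y) - 0.5 * float(b @ (dinv * b))

    f = pen_ll(b)
    cf = None
    for _ in range(max_iter):
        eta = xb + Z @ b
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        g = Z.T @ (y - mu) - dinv * b
        H = (Z * w[:, None]).T @ Z
        H[np.diag_indices_from(H)] += dinv
        cf = cho_factor(H, lower=True)
        step = cho_solve(cf, g)
        # step halving
        t = 1.0
        for _ in range(30):
            b_new = b + t * step
            f_new = pen_ll(b_new)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        b, f = b_new, f_new
        if np.max(np.abs(g)) < tol:
            break
    # recompute curvature at the mode
    eta = xb + Z @ b
    mu = special.expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = (Z * w[:, None]).T @ Z
    H[np.diag_indices_from(H)] += dinv
    cf = cho_factor(H, lower=True)
    return b, cf, f


def _laplace_nll(params, X, y, Z, sizes, cache):
    p = X.shape[1]
    beta = params[:p]
    logsd = params[p:]
    dinv = np.repeat(np.exp(-2.0 * logsd), sizes)
    xb = X @ beta
    b, cf, f = _inner_mode(xb, y, Z, dinv, cache["b"])
    cache["b"] = b
    logdet_D = 2.0 * float(sizes @ logsd)
    logdet_H = 2.0 * float(np.log(np.diag(cf[0])).sum())
    return -(f - 0.5 * logdet_D - 0.5 * logdet_H)


def _plain_logistic(X, y, tol=1e-10, max_iter=100):
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        g = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(g)) < tol or np.max(np.abs(step)) > 1e6:
            break
    return beta


class BinomialGLMM(BaseEstimator):
    """Mixed-effects logistic regression, Laplace marginal likelihood.

    Parameters
    ----------
    fit_intercept : bool
        Prepend an intercept column to ``X``.
    tol : float
        Gradient tolerance declared for convergence of the outer optimiser.
    max_iter : int
        Outer iteration cap.
    multi_start : bool
        Start the outer optimiser from a fixed 3-point grid of log-SD values
        (deterministic); the best final objective wins.  With ``False`` a
        single moderate start is used.

    Attributes
    ----------
    params_ : (p,) fixed-effect estimates (intercept first if requested).
    se_ : standard errors from the Laplace observed-information Schur
        complement.
    vc_ : (k,) variance components, one per grouping factor.
    ranef_ : conditional modes of the random intercepts (concatenated).
    loglik_ : maximised Laplace marginal log-likelihood.
    converged_ : bool.
    separation_ : bool, True when the likelihood shows signs of complete
        separation (unbounded fixed effects).
    """

    def __init__(self, *, fit_intercept=True, tol=1e-6, max_iter=200,
                 multi_start=True):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter
        self.multi_start = multi_start

    def fit(self, X, y, groups=None):
        X = _add_intercept(X, self.fit_intercept)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError("X and y have incompatible shapes")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("response must be binary 0/1")
        codes, levels = _as_groups(groups, n)
        k = codes.shape[1]
        if n < p + 2:
            raise ValueError("need at least n_fixed + 2 observations")

        beta0 = _plain_logistic(X, y)

        if k == 0:
            beta = _plain_logistic(X, y)
            eta = X @ beta
            mu = special.expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            cov = np.linalg.inv((X * w[:, None]).T @ X)
            self.params_ = beta
            self.se_ = np.sqrt(np.diag(cov))
            self.vc_ = np.zeros(0)
            self.ranef_ = np.zeros(0)
            self.group_sizes_ = np.zeros(0, dtype=int)
            self.loglik_ = _bernoulli_loglik(eta, y)
            self.converged_ = True
            self._check_separation(X, y, beta)
            self._finalize(X, y, codes, levels)
            return self

        Z, sizes = _dense_Z(codes)
        cache = {"b": np.zeros(Z.shape[1])}
        args = (X, y, Z, sizes, cache)
        bounds = [(None, None)] * p + [(_LOGSD_LO, _LOGSD_HI)] * k

        starts = _MULTISTART if self.multi_start else (-0.5,)
        best = None
        for s in starts:
            cache["b"] = np.zeros(Z.shape[1])
            x0 = np.concatenate([beta0, np.full(k, s)])
            res = optimize.minimize(
                _laplace_nll, x0, args=args, method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": self.max_iter, "ftol": 1e-11,
                         "gtol": self.tol},
            )
            if best is None or res.fun < best.fun - 1e-9:
                best = res
        res = best

        beta = res.x[:p]
        logsd = res.x[p:]
        dinv = np.repeat(np.exp(-2.0 * logsd), sizes)
        b, cf, _ = _inner_mode(X @ beta, y, Z, dinv, cache["b"])

        # cov(beta): Schur complement of the joint (beta, b) curvature
        eta = X @ beta + Z @ b
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        Xw = X * w[:, None]
        A = Xw.T @ X
        B = Xw.T @ Z
        S = A - B @ cho_solve(cf, B.T)
        try:
            cov = np.linalg.inv(S)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)

        self.params_ = beta
        self.se_ = se
        self.vc_ = np.exp(2.0 * logsd)
        self.ranef_ = b
        self.group_sizes_ = sizes
        self.loglik_ = -res.fun
        self.converged_ = bool(res.success)
        if not self.converged_:
            warnings.warn("outer optimiser did not report convergence",
                          ConvergenceWarning, stacklevel=2)
        self._check_separation(X, y, beta)
        self._finalize(X, y, codes, levels)
        return self

    def _check_separation(self, X, y, beta):
        # separation diagnostic: fitted probabilities saturate and match y
        slopes = beta[1:] if self.fit_intercept else beta
        eta_fix = X @ beta
        saturated = (np.abs(eta_fix) > 15).all() and np.allclose(
            (eta_fix > 0).astype(float), y)
        self.separation_ = bool(saturated or np.any(np.abs(slopes) > 25))
        if self.separation_:
            warnings.warn(
                "possible complete separation: fixed-effect estimates are "
                "unbounded; interpret this fit with caution",
                SeparationWarning, stacklevel=2)

    def _finalize(self, X, y, codes, levels):
        self._X, self._y, self._codes = X, y, codes
        self.n_obs_ = X.shape[0]
        self.n_groups_ = [len(l) for l in levels]
        self.group_levels_ = levels
        if self.fit_intercept:
            self.intercept_ = self.params_[0]
            self.coef_ = self.params_[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = self.params_
        if not hasattr(self, "separation_"):
            self.separation_ = False

    def predict_proba(self, X):
        """Population-level probabilities (random effects at zero)."""
        X = _add_intercept(X, self.fit_intercept)
        p1 = special.expit(X @ self.params_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# --------------------------------------------------------------------------
# Gaussian LMM (REML / ML)
# --------------------------------------------------------------------------

_LOG2PI = np.log(2.0 * np.pi)


def _lmm_profiled_nll(loglam, X, y, ZZts, reml):
    """Negative profiled (restricted) log-likelihood.

    loglam are log ratios sigma_k / sigma_e; the residual variance and the
    GLS fixed effects are profiled out in closed form.
    """
    n, p = X.shape
    V0 = np.eye(n)
    for ll, ZZt in zip(loglam, ZZts):
        V0 += np.exp(2.0 * ll) * ZZt
    try:
        cf = cho_factor(V0, lower=True)
    except np.linalg.LinAlgError:
        return np.inf
    logdetV0 = 2.0 * float(np.log(np.diag(cf[0])).sum())
    ViX = cho_solve(cf, X)
    Viy = cho_solve(cf, y)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    r = y - X @ beta
    rss = float(r @ cho_solve(cf, r))
    if rss <= 0:
        return np.inf
    if reml:
        s2 = rss / (n - p)
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        nll = 0.5 * ((n - p) * (np.log(s2) + _LOG2PI + 1.0)
                     + logdetV0 + logdetXtViX)
    else:
        s2 = rss / n
        nll = 0.5 * (n * (np.log(s2) + _LOG2PI + 1.0) + logdetV0)
    return nll


def _lmm_point(loglam, X, y, ZZts, reml):
    """Estimates at a given variance-ratio configuration."""
    n, p = X.shape
    V0 = np.eye(n)
    for ll, ZZt in zip(loglam, ZZts):
        V0 += np.exp(2.0 * ll) * ZZt
    cf = cho_factor(V0, lower=True)
    ViX = cho_solve(cf, X)
    Viy = cho_solve(cf, y)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    r = y - X @ beta
    rss = float(r @ cho_solve(cf, r))
    s2 = rss / (n - p) if reml else rss / n
    cov_beta = s2 * np.linalg.inv(XtViX)
    return beta, cov_beta, s2, cf


class GaussianLMM(BaseEstimator):
    """Linear mixed model with crossed random intercepts.

    Variance components are estimated by REML (default) or ML on the
    profiled likelihood: the residual variance and the GLS fixed effects
    have closed forms at every candidate variance-ratio point, so the outer
    search runs over ``k`` log-ratios only.

    Attributes follow :class:`BinomialGLMM`; additionally ``sigma2_`` is the
    residual variance and ``method`` records "reml" or "ml".
    """

    def __init__(self, *, fit_intercept=True, method="reml", tol=1e-8,
                 max_iter=200, multi_start=True):
        self.fit_intercept = fit_intercept
        self.method = method
        self.tol = tol
        self.max_iter = max_iter
        self.multi_start = multi_start

    def fit(self, X, y, groups=None):
        if self.method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")
        reml = self.method == "reml"
        X = _add_intercept(X, self.fit_intercept)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError("X and y have incompatible shapes")
        if not np.isfinite(y).all():
            raise ValueError("response contains non-finite values")
        # collinearity guard on the fixed design
        sv = np.linalg.svd(X, compute_uv=False)
        if p > 1 and sv[-1] < 1e-8 * max(sv[0], 1.0):
            raise ValueError("singular fixed-effect design (collinear "
                             "predictor columns)")
        codes, levels = _as_groups(groups, n)
        k = codes.shape[1]

        if k == 0:
            beta, cov_beta, s2, _ = _lmm_point(np.zeros(0), X, y, [], reml)
            self.params_, self._cov_beta = beta, cov_beta
            self.se_ = np.sqrt(np.diag(cov_beta))
            self.vc_ = np.zeros(0)
            self.sigma2_ = s2
            self.loglik_ = -_lmm_profiled_nll(np.zeros(0), X, y, [], reml)
            self.converged_ = True
            self._finalize(X, y, codes, levels, [])
            return self

        Z, sizes = _dense_Z(codes)
        ZZts = []
        off = 0
        for sz in sizes:
            Zk = Z[:, off:off + sz]
            ZZts.append(Zk @ Zk.T)
            off += sz
        args = (X, y, ZZts, reml)
        bounds = [(_LOGSD_LO, _LOGSD_HI)] * k
        starts = _MULTISTART if self.multi_start else (-0.5,)
        best = None
        for s in starts:
            res = optimize.minimize(
                _lmm_profiled_nll, np.full(k, s), args=args,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": self.max_iter, "ftol": 1e-13,
                         "gtol": self.tol},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        res = best

        loglam = res.x
        beta, cov_beta, s2, cf = _lmm_point(loglam, X, y, ZZts, reml)
        self.params_ = beta
        self._cov_beta = cov_beta
        self.se_ = np.sqrt(np.diag(cov_beta))
        self.sigma2_ = s2
        self.vc_ = np.exp(2.0 * loglam) * s2
        self.loglik_ = -res.fun
        self.converged_ = bool(res.success)
        if not self.converged_:
            warnings.warn("outer optimiser did not report convergence",
                          ConvergenceWarning, stacklevel=2)
        self.boundary_ = loglam <= _LOGSD_LO + 1e-6
        self._finalize(X, y, codes, levels, ZZts)
        return self

    def _finalize(self, X, y, codes, levels, ZZts):
        self._X, self._y, self._codes, self._ZZts = X, y, codes, ZZts
        self.n_obs_ = X.shape[0]
        self.n_groups_ = [len(l) for l in levels]
        self.group_levels_ = levels
        self.group_sizes_ = np.asarray([len(l) for l in levels], dtype=int)
        if self.fit_intercept:
            self.intercept_ = self.params_[0]
            self.coef_ = self.params_[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = self.params_
        if not hasattr(self, "boundary_"):
            self.boundary_ = np.zeros(len(levels), dtype=bool)

    def predict(self, X):
        """Population-level predictions (random effects at zero)."""
        X = _add_intercept(X, self.fit_intercept)
        return X @ self.params_

    def refit(self, method):
        """Refit the same data under a different estimation criterion."""
        est = GaussianLMM(fit_intercept=False, method=method, tol=self.tol,
                          max_iter=self.max_iter,
                          multi_start=self.multi_start)
        groups = self._codes if self._codes.shape[1] else None
        return est.fit(self._X, self._y, groups=groups)


# --------------------------------------------------------------------------
# Inference helpers for the Gaussian family
# --------------------------------------------------------------------------

def _reml_nll_raw(theta, X, y, ZZts):
    """Unprofiled REML negative log-likelihood on the raw variance scale.

    theta = (sigma_1^2, ..., sigma_k^2, sigma_e^2).
    """
    n, p = X.shape
    k = len(ZZts)
    if np.any(np.asarray(theta[:-1]) < 0) or theta[-1] <= 0:
        return np.inf
    V = theta[-1] * np.eye(n)
    for t, ZZt in zip(theta[:k], ZZts):
        V += t * ZZt
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return np.inf
    logdetV = 2.0 * float(np.log(np.diag(cf[0])).sum())
    ViX = cho_solve(cf, X)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, X.T @ cho_solve(cf, y))
    r = y - X @ beta
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    return 0.5 * (logdetV + logdetXtViX + float(r @ cho_solve(cf, r))
                  + (n - p) * _LOG2PI)


def _contrast_var(theta, X, ZZts, c):
    n = X.shape[0]
    k = len(ZZts)
    V = theta[-1] * np.eye(n)
    for t, ZZt in zip(theta[:k], ZZts):
        V += t * ZZt
    cf = cho_factor(V, lower=True)
    XtViX = X.T @ cho_solve(cf, X)
    return float(c @ np.linalg.solve(XtViX, c))


def satterthwaite_df(model: GaussianLMM, c):
    """Satterthwaite denominator degrees of freedom for the contrast c'beta.

    Uses the delta method: df = 2 v^2 / Var(v), with v the variance of the
    contrast as a function of the variance components and Var from the
    inverse REML observed information (numerical Hessian).  Components at
    the zero boundary are held fixed; with no free random components the
    classical residual df ``n - p`` is returned exactly.
    """
    X, y, ZZts = model._X, model._y, model._ZZts
    n, p = X.shape
    c = np.asarray(c, dtype=float)
    theta = np.concatenate([model.vc_, [model.sigma2_]])
    free = [i for i, t in enumerate(theta[:-1])
            if t > 1e-6 * model.sigma2_] + [len(theta) - 1]
    if len(free) == 1 and len(ZZts) > 0 and all(
            t <= 1e-6 * model.sigma2_ for t in theta[:-1]):
        return float(n - p)
    if not ZZts:
        return float(n - p)

    def nll_free(tf):
        full = theta.copy()
        full[free] = tf
        return _reml_nll_raw(full, X, y, ZZts)

    def v_free(tf):
        full = theta.copy()
        full[free] = tf
        return _contrast_var(full, X, ZZts, c)

    t0 = theta[free]
    # central-difference steps must not cross the zero-variance boundary
    h = np.minimum(np.maximum(1e-8, 1e-4 * np.abs(t0)), t0 / 2.0)
    m = len(free)
    H = np.empty((m, m))
    f0 = nll_free(t0)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            if i == j:
                H[i, i] = (nll_free(t0 + ei) - 2 * f0 + nll_free(t0 - ei)) \
                    / (h[i] ** 2)
            else:
                H[i, j] = H[j, i] = (
                    nll_free(t0 + ei + ej) - nll_free(t0 + ei - ej)
                    - nll_free(t0 - ei + ej) + nll_free(t0 - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov_theta = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_theta = np.linalg.pinv(H)

    g = np.empty(m)
    for i in range(m):
        ei = np.zeros(m); ei[i] = h[i]
        g[i] = (v_free(t0 + ei) - v_free(t0 - ei)) / (2 * h[i])
    v = v_free(t0)
    denom = float(g @ cov_theta @ g)
    if denom <= 0 or not np.isfinite(denom):
        return float(n - p)
    df = 2.0 * v * v / denom
    return float(np.clip(df, 1.0, n - p))


def wald_f_test(model: GaussianLMM, index, df_method="satterthwaite"):
    """Single-coefficient F test with approximate denominator df.

    ``index`` addresses the column of the full fixed design (intercept
    first when present).  ``df_method`` accepts "satterthwaite" or "kr";
    the Kenward-Roger request currently falls back to Satterthwaite with a
    warning, and the method actually used is returned.
    """
    method = df_method.lower()
    if method in ("kr", "kenward-roger"):
        warnings.warn(
            "Kenward-Roger adjustment not implemented; using Satterthwaite "
            "denominator degrees of freedom",
            UserWarning, stacklevel=2)
        method = "satterthwaite"
    if method != "satterthwaite":
        raise ValueError(f"unknown df_method {df_method!r}")
    p = model.params_.shape[0]
    c = np.zeros(p)
    c[index] = 1.0
    est = model.params_[index]
    se = model.se_[index]
    F = (est / se) ** 2
    df2 = satterthwaite_df(model, c)
    pval = float(stats.f.sf(F, 1, df2))
    return float(F), 1, float(df2), pval, "F-Satterthwaite"
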