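"""Model specifications and inference on contest designs.

Thin DataFrame-facing layer over :mod:`contestkit.estimators`: a
:class:`ModelSpec` names the response, fixed predictors and crossed
random-intercept factors by column; fitting returns a
:class:`FittedMixedModel` that carries the estimates, variance components
and the log-likelihood needed for likelihood-ratio and F tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import BinomialGLMM, GaussianLMM, wald_f_test

__all__ = [
    "ModelSpec",
    "FittedMixedModel",
    "TestResult",
    "fit_binomial_glmm",
    "fit_gaussian_lmm",
    "likelihood_ratio_test",
    "fixed_effect_f_test",
    "collinearity_report",
]


@dataclass(frozen=True)
class ModelSpec:
    """Response, fixed predictors and crossed random-intercept factors."""

    response: str
    family: str  # "binomial" | "gaussian"
    fixed: tuple = ()
    random_intercept_factors: tuple = ()

    def __post_init__(self):
        if self.family not in ("binomial", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "random_intercept_factors",
                           tuple(self.random_intercept_factors))
        if len(self.fixed) > 2:
            raise ValueError("at most two fixed predictors are supported")
        rif = self.random_intercept_factors
        if len(set(rif)) != len(rif):
            raise ValueError("grouping factors must be distinct")

    def nests_in(self, other: "ModelSpec") -> bool:
        return (self.response == other.response
                and self.family == other.family
                and self.random_intercept_factors
                == other.random_intercept_factors
                and set(self.fixed) <= set(other.fixed))


@dataclass
class FittedMixedModel:
    """One mixed-model fit: estimates, variance components, likelihood."""

    spec: ModelSpec
    beta: dict                 # name -> (estimate, se); "(intercept)" first
    variance_components: dict  # factor name -> variance
    residual_variance: float | None
    loglik: float
    method: str                # "laplace-ml" | "reml" | "ml"
    converged: bool
    n_obs: int
    n_groups: dict
    estimator: object = field(repr=False, default=None)
    warnings: tuple = ()

    @property
    def n_fixed_params(self) -> int:
        return len(self.beta)

    def slope(self, name: str) -> float:
        return self.beta[name][0]

    def slope_se(self, name: str) -> float:
        return self.beta[name][1]


@dataclass(frozen=True)
class TestResult:
    """A single inferential result (LR chi-square or approximate F)."""

    method: str        # "LR-chisq" | "F-Satterthwaite" | "F-KR"
    statistic: float
    df1: float
    p_value: float
    df2: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")
        if self.statistic < 0:
            raise ValueError("test statistic must be nonnegative")


def _design_from(data: pd.DataFrame, spec: ModelSpec):
    cols = [spec.response, *spec.fixed, *spec.random_intercept_factors]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns absent from data: {missing}")
    sub = data[cols].dropna()
    y = sub[spec.response].to_numpy(dtype=float)
    X = sub[list(spec.fixed)].to_numpy(dtype=float) if spec.fixed \
        else np.empty((len(sub), 0))
    groups = sub[list(spec.random_intercept_factors)].to_numpy() \
        if spec.random_intercept_factors else None
    return X, y, groups, sub


def _pack(spec, est, method, extra_warnings=()):
    names = ["(intercept)", *spec.fixed]
    beta = {nm: (float(b), float(s))
            for nm, b, s in zip(names, est.params_, est.se_)}
    vcs = {f: float(v) for f, v in
           zip(spec.random_intercept_factors, est.vc_)}
    ngroups = {f: int(g) for f, g in
               zip(spec.random_intercept_factors, est.n_groups_)}
    return FittedMixedModel(
        spec=spec, beta=beta, variance_components=vcs,
        residual_variance=float(getattr(est, "sigma2_", np.nan))
        if spec.family == "gaussian" else None,
        loglik=float(est.loglik_), method=method,
        converged=bool(est.converged_), n_obs=int(est.n_obs_),
        n_groups=ngroups, estimator=est, warnings=tuple(extra_warnings))


def fit_binomial_glmm(data: pd.DataFrame, spec: ModelSpec,
                      control: dict | None = None) -> FittedMixedModel:
    """Fit a mixed-effects logistic regression by Laplace ML."""
    if spec.family != "binomial":
        raise ValueError("spec.family must be 'binomial'")
    X, y, groups, _ = _design_from(data, spec)
    est = BinomialGLMM(**(control or {}))
    extra = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        est.fit(X, y, groups=groups)
        extra = [str(w.message) for w in caught]
    return _pack(spec, est, "laplace-ml", extra)


def fit_gaussian_lmm(data: pd.DataFrame, spec: ModelSpec,
                     control: dict | None = None,
                     method: str = "reml") -> FittedMixedModel:
    """Fit a Gaussian linear mixed model by REML (default) or ML."""
    if spec.family != "gaussian":
        raise ValueError("spec.family must be 'gaussian'")
    X, y, groups, _ = _design_from(data, spec)
    est = GaussianLMM(method=method, **(control or {}))
    extra = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        est.fit(X, y, groups=groups)
        extra = [str(w.message) for w in caught]
    return _pack(spec, est, method, extra)


def _refit_ml_multistart(model: FittedMixedModel) -> float:
    """ML log-likelihood of a model refit from the full multi-start grid."""
    est = model.estimator
    groups = est._codes if est._codes.shape[1] else None
    if model.spec.family == "binomial":
        new = BinomialGLMM(fit_intercept=False, multi_start=True)
    else:
        new = GaussianLMM(fit_intercept=False, method="ml",
                          multi_start=True)
    return float(new.fit(est._X, est._y, groups=groups).loglik_)


def likelihood_ratio_test(full: FittedMixedModel,
                          reduced: FittedMixedModel) -> TestResult:
    """LR chi-square test of nested fixed-effect structures.

    Both models must be ML fits of the same response and random structure;
    Gaussian REML fits are refit by ML automatically, since restricted
    likelihoods of models with different fixed effects are not comparable.
    """
    if not reduced.spec.nests_in(full.spec):
        raise ValueError("reduced model spec does not nest in the full "
                         "model spec")
    full_ll, red_ll = full.loglik, reduced.loglik
    if full.spec.family == "gaussian":
        if full.method == "reml":
            full_ll = full.estimator.refit("ml").loglik_
        if reduced.method == "reml":
            red_ll = reduced.estimator.refit("ml").loglik_
    df1 = full.n_fixed_params - reduced.n_fixed_params
    if df1 <= 0:
        stat = max(0.0, 2.0 * (full_ll - red_ll))
        return TestResult("LR-chisq", stat, 0, 1.0)
    stat = 2.0 * (full_ll - red_ll)
    if stat < -1e-4:
        # the full fit missed its optimum; retry from the multi-start grid
        full_ll = max(full_ll, _refit_ml_multistart(full))
        stat = 2.0 * (full_ll - red_ll)
    if stat < -1e-4:
        raise RuntimeError(
            f"reduced model log-likelihood exceeds the full model's by "
            f"{-stat / 2:.4g} even after multi-start refitting")
    stat = max(0.0, stat)
    p = float(stats.chi2.sf(stat, df1))
    return TestResult("LR-chisq", stat, df1, p)


def fixed_effect_f_test(model: FittedMixedModel, predictor: str,
                        df_method: str = "satterthwaite") -> TestResult:
    """Approximate F test for a single fixed effect of a Gaussian LMM."""
    if model.spec.family != "gaussian":
        raise ValueError("F tests apply to the Gaussian family only")
    if predictor not in model.spec.fixed:
        raise KeyError(f"{predictor!r} is not a fixed effect of the model")
    index = 1 + model.spec.fixed.index(predictor)  # after intercept
    F, df1, df2, p, used = wald_f_test(model.estimator, index,
                                       df_method=df_method)
    return TestResult(used, F, df1, p, df2=df2)


def collinearity_report(data: pd.DataFrame, columns) -> pd.DataFrame:
    """Pairwise Pearson correlations with a high-collinearity flag.

    Returns one row per unordered pair with columns ``a, b, r, flagged,
    note``; constant columns yield an undefined correlation, reported as
    such rather than raising.  The flag threshold |r| > 0.7 drives the
    one-predictor-per-model policy of the duration analysis.
    """
    columns = list(columns)
    if len(columns) < 2:
        raise ValueError("need at least two columns")
    sub = data[columns].dropna()
    if len(sub) < 3:
        raise ValueError("need at least three complete rows")
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            xa, xb = sub[a].to_numpy(float), sub[b].to_numpy(float)
            if np.std(xa) == 0 or np.std(xb) == 0:
                rows.append({"a": a, "b": b, "r": np.nan, "flagged": False,
                             "note": "undefined (constant column)"})
                continue
            r = float(np.corrcoef(xa, xb)[0, 1])
            rows.append({"a": a, "b": b, "r": r,
                         "flagged": bool(abs(r) > 0.7), "note": ""})
    return pd.DataFrame(rows)
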