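"""Two-step assessment diagnosis for dyadic contests.

Step 1 (*victory screen*): for each candidate power measure, a mixed
logistic regression of contest outcome on the focal-vs-opponent relative
power difference, with crossed random intercepts for focal and opponent
identity, decides whether the measure is a genuine RHP correlate — a
significantly positive RPD slope.

Step 2 (*duration pattern*): for each screened measure, three Gaussian
mixed models of log10 duration — on winner power, loser power and
winner-vs-loser relative power, one predictor at a time because the three
are typically collinear — yield the slope pattern from which the
assessment mode is classified:

* duration falling with winner RHP while rising with loser RHP is the
  signature of mutual assessment, though cumulative damage (CAM) can mimic
  it, so the verdict is "mutual-or-CAM";
* duration rising with *both* sides' RHP rules mutual assessment out: the
  contest is settled by attrition, labelled "pure-self-assessment" when the
  loser's (standardized) slope dominates and "winner-dominated-attrition"
  when the winner's does;
* one significant positive slope plus a positive trend on the other side
  still rules mutual assessment out ("mutual-ruled-out-attrition");
* anything else is "inconclusive".

The relative-power slope never drives the verdict — a negative
duration-vs-RPD association can arise spuriously — and is recorded in the
rationale only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed import (ModelSpec, TestResult, fit_binomial_glmm,
                    fit_gaussian_lmm, fixed_effect_f_test,
                    likelihood_ratio_test)
from .prep import (MEASURES, assign_focal_roles, balance_check,
                   build_duration_design, standardize_column)

__all__ = [
    "VictoryScreenResult",
    "DurationPattern",
    "DiagnosticVerdict",
    "screen_rhp_correlates",
    "classify_assessment",
    "run_two_step",
    "CATEGORIES",
]

CATEGORIES = ("mutual-or-CAM", "pure-self-assessment",
              "mutual-ruled-out-attrition", "winner-dominated-attrition",
              "inconclusive")

SELF_ASSESSMENT_FAMILY = ("pure-self-assessment",
                          "winner-dominated-attrition",
                          "mutual-ruled-out-attrition")


@dataclass(frozen=True)
class VictoryScreenResult:
    measure: str
    slope: float
    lr_test: TestResult | None
    is_rhp_correlate: bool
    note: str = ""


@dataclass(frozen=True)
class SlopeResult:
    slope: float           # raw-scale slope
    slope_std: float       # slope on the z-standardized predictor
    test: TestResult


@dataclass(frozen=True)
class DurationPattern:
    measure: str
    winner: SlopeResult
    loser: SlopeResult
    relative: SlopeResult


@dataclass(frozen=True)
class DiagnosticVerdict:
    measure: str
    category: str
    rationale: str
    alpha_used: float
    trend_alpha_used: float


def screen_rhp_correlates(victory_fits: dict, alpha: float = 0.05):
    """Flag measures whose RPD slope is significantly positive.

    ``victory_fits`` maps measure name to ``(slope, TestResult)``; a
    missing or None test leaves the measure unscreened.  A significant
    *negative* slope is anomalous — the measure predicts defeat — and is
    reported as such, never as a correlate.
    """
    results = []
    for measure, entry in victory_fits.items():
        if entry is None or entry[1] is None:
            results.append(VictoryScreenResult(measure, np.nan, None,
                                               False, "unscreened"))
            continue
        slope, test = entry
        sig = test.p_value < alpha
        if sig and slope > 0:
            results.append(VictoryScreenResult(measure, slope, test, True))
        elif sig and slope < 0:
            results.append(VictoryScreenResult(
                measure, slope, test, False,
                "anomalous: significant negative victory slope"))
        else:
            results.append(VictoryScreenResult(measure, slope, test, False))
    return results


def _sig_pos(s: SlopeResult, alpha):
    return s.slope > 0 and s.test.p_value < alpha


def _sig_neg(s: SlopeResult, alpha):
    return s.slope < 0 and s.test.p_value < alpha


def _trend_pos(s: SlopeResult, trend_alpha):
    return s.slope > 0 and s.test.p_value < trend_alpha


def classify_assessment(pattern: DurationPattern, alpha: float = 0.05,
                        trend_alpha: float = 0.10) -> DiagnosticVerdict:
    """Map a winner/loser/relative slope pattern to an assessment verdict.

    Rules are applied in a fixed order; the relative-power slope is noted
    in the rationale but never changes the category.  Pure function of the
    pattern and the two thresholds.
    """
    if not (0 < alpha < trend_alpha < 1):
        raise ValueError("need 0 < alpha < trend_alpha < 1")
    w, l, r = pattern.winner, pattern.loser, pattern.relative
    rel_note = (f"relative-power slope {r.slope:+.3g} "
                f"(p={r.test.p_value:.3g}) recorded but not used")

    if _sig_neg(w, alpha) and _sig_pos(l, alpha):
        cat = "mutual-or-CAM"
        why = ("winner slope significantly negative and loser slope "
               "significantly positive: the mutual-assessment signature, "
               "which cumulative damage can mimic")
    elif _sig_pos(w, alpha) and _sig_pos(l, alpha):
        if abs(l.slope_std) > abs(w.slope_std):
            cat = "pure-self-assessment"
            why = ("both slopes significantly positive, loser's "
                   "standardized slope dominates: mutual assessment ruled "
                   "out, classic attrition")
        else:
            cat = "winner-dominated-attrition"
            why = ("both slopes significantly positive, winner's "
                   "standardized slope at least as large: mutual "
                   "assessment ruled out, attrition extended by winners")
    elif (_sig_pos(w, alpha) and _trend_pos(l, trend_alpha)) or \
         (_sig_pos(l, alpha) and _trend_pos(w, trend_alpha)):
        cat = "mutual-ruled-out-attrition"
        why = ("one side significantly positive, the other a positive "
               "trend: both slopes positive, mutual assessment ruled out")
    else:
        cat = "inconclusive"
        why = "no decision rule fired on the slope pattern"
    return DiagnosticVerdict(
        measure=pattern.measure, category=cat,
        rationale=f"{why}; winner {w.slope:+.3g} (p={w.test.p_value:.3g}), "
                  f"loser {l.slope:+.3g} (p={l.test.p_value:.3g}); "
                  f"{rel_note}",
        alpha_used=alpha, trend_alpha_used=trend_alpha)


def _victory_fit(assigned: pd.DataFrame, measure: str, control,
                 reduced_cache: dict):
    """Full and reduced victory GLMMs; returns (fit, slope, slope_std, LR).

    The reduced (intercept + random intercepts) model depends only on the
    retained rows, not on the measure, so it is cached per row subset.
    """
    col = f"rpd_{measure}"
    data = assigned.dropna(subset=[col]).copy()
    mu, sd = standardize_column(data, col)
    spec_full = ModelSpec("outcome", "binomial", (col + "_std",),
                          ("focal_state", "opponent_state"))
    spec_red = ModelSpec("outcome", "binomial", (),
                         ("focal_state", "opponent_state"))
    full = fit_binomial_glmm(data, spec_full, control)
    key = tuple(data.index)
    if key not in reduced_cache:
        reduced_cache[key] = fit_binomial_glmm(data, spec_red, control)
    lr = likelihood_ratio_test(full, reduced_cache[key])
    slope_std = full.slope(col + "_std")
    return full, slope_std / sd, slope_std, lr


def _duration_fits(dyads: pd.DataFrame, measure: str, control,
                   df_method: str, rpd_kind: str):
    design, _ = build_duration_design(dyads, measure, rpd_kind=rpd_kind)
    out = {}
    for predictor in ("winner_power", "loser_power", "relative_power"):
        mu, sd = standardize_column(design, predictor)
        spec = ModelSpec("log10_duration", "gaussian",
                         (predictor + "_std",),
                         ("winner_state", "loser_state"))
        fit = fit_gaussian_lmm(design, spec, control)
        test = fixed_effect_f_test(fit, predictor + "_std",
                                   df_method=df_method)
        slope_std = fit.slope(predictor + "_std")
        out[predictor] = SlopeResult(slope=slope_std / sd,
                                     slope_std=slope_std, test=test)
        if not fit.converged:
            out[predictor + "_warning"] = "non-convergence"
    return out


def run_two_step(dyads: pd.DataFrame, measures=MEASURES,
                 alpha: float = 0.05, trend_alpha: float = 0.10,
                 min_dyads: int = 10, tie_break: str = "war_id",
                 rpd_kind: str = "bounded", df_method: str = "satterthwaite",
                 control: dict | None = None,
                 screen_override: bool = False,
                 duration_measures=None) -> dict:
    """Full two-step analysis of a dyad table.

    Assignment -> per-measure victory GLMM + LR screen -> three
    single-predictor duration LMMs per screened measure -> verdict.
    ``screen_override=True`` runs the duration analysis for every measure
    regardless of the screen; ``duration_measures`` restricts the duration
    stage to a subset of the screened measures (all of them by default).
    Returns a consolidated report dict.
    """
    if len(dyads) == 0:
        raise ValueError("empty dyad table")
    if len(dyads) < min_dyads:
        raise ValueError(
            f"{len(dyads)} dyads < configured floor of {min_dyads}")
    assigned = assign_focal_roles(dyads, tie_break=tie_break,
                                  measures=measures, rpd_kind=rpd_kind)
    balance = balance_check(assigned)

    victory_fits, screen_inputs, victory_detail = {}, {}, {}
    reduced_cache: dict = {}
    for m in measures:
        col = f"rpd_{m}"
        if col not in assigned.columns or \
                assigned[col].notna().sum() < min_dyads:
            screen_inputs[m] = None
            continue
        try:
            fit, slope_raw, slope_std, lr = _victory_fit(
                assigned, m, control, reduced_cache)
        except Exception as exc:  # noqa: BLE001 - reported, not fatal
            screen_inputs[m] = None
            victory_detail[m] = {"error": str(exc)}
            continue
        victory_fits[m] = fit
        victory_detail[m] = {"slope": slope_raw, "slope_std": slope_std,
                             "lr": lr, "converged": fit.converged}
        screen_inputs[m] = (slope_std, lr)

    screen = {r.measure: r
              for r in screen_rhp_correlates(screen_inputs, alpha=alpha)}

    patterns, verdicts = {}, {}
    for m in measures:
        if duration_measures is not None and m not in duration_measures:
            continue
        if not screen_override and not screen[m].is_rhp_correlate:
            continue
        try:
            fits = _duration_fits(dyads, m, control, df_method, rpd_kind)
        except Exception as exc:  # noqa: BLE001
            verdicts[m] = DiagnosticVerdict(
                m, "inconclusive",
                f"duration models failed: {exc}", alpha, trend_alpha)
            continue
        pattern = DurationPattern(m, fits["winner_power"],
                                  fits["loser_power"],
                                  fits["relative_power"])
        patterns[m] = pattern
        if any(k.endswith("_warning") for k in fits):
            verdicts[m] = DiagnosticVerdict(
                m, "inconclusive",
                "inconclusive-with-warning: a duration model did not "
                "converge", alpha, trend_alpha)
        else:
            verdicts[m] = classify_assessment(pattern, alpha=alpha,
                                              trend_alpha=trend_alpha)

    return {
        "n_dyads": int(len(dyads)),
        "balance": balance,
        "victory": victory_detail,
        "screen": screen,
        "no_rhp_correlates": not any(r.is_rhp_correlate
                                     for r in screen.values()),
        "patterns": patterns,
        "verdicts": verdicts,
        "alpha": alpha,
        "trend_alpha": trend_alpha,
    }
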