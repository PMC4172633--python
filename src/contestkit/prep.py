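"""Contest-dyad preparation: analysis designs for victory and duration.

A dyad table has one row per contest with columns ``war_id, winner_state,
loser_state, duration_days, winner_entry_year, loser_entry_year`` plus a
``winner_<m>`` / ``loser_<m>`` pair for each power measure ``m`` (the
canonical five: pec, milper, tpop, upop, cinc).

Two designs are produced:

* the balanced focal/opponent *victory design*: each contest's winner is
  alternately labelled focal or opponent down the duration-ordered list, so
  focal status carries no information about winning, and the signed
  relative power difference (RPD) of focal vs opponent is the predictor of
  a binary outcome;
* the *duration design*: log10 duration against winner power, loser power
  and winner-vs-loser RPD, modelled one predictor at a time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

MEASURES = ("pec", "milper", "tpop", "upop", "cinc")

__all__ = [
    "MEASURES",
    "relative_power_difference",
    "assign_focal_roles",
    "balance_check",
    "build_duration_design",
    "standardize_column",
]


def relative_power_difference(p_i, p_j, kind: str = "bounded"):
    """Signed relative power difference of side i against side j.

    The bounded contrast ``(p_i - p_j) / (p_i + p_j)`` lies in (-1, 1),
    is antisymmetric in its arguments and positive exactly when side i is
    the stronger; a log-ratio variant ``log(p_i / p_j)`` (unbounded, same
    sign convention) is available for sensitivity analysis.

    Scalar or array inputs; both powers zero (or either zero under the
    log-ratio) is a domain error.
    """
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    if np.any(p_i < 0) or np.any(p_j < 0):
        raise ValueError("powers must be nonnegative")
    if kind == "bounded":
        tot = p_i + p_j
        if np.any(tot == 0):
            raise ValueError("relative power difference undefined: both "
                             "sides have zero power")
        out = (p_i - p_j) / tot
    elif kind == "logratio":
        if np.any(p_i == 0) or np.any(p_j == 0):
            raise ValueError("log-ratio undefined for zero power")
        out = np.log(p_i / p_j)
    else:
        raise ValueError(f"unknown RPD kind {kind!r}")
    return float(out) if out.ndim == 0 else out


def _require_dyad_columns(dyads: pd.DataFrame):
    needed = {"war_id", "winner_state", "loser_state", "duration_days"}
    missing = needed - set(dyads.columns)
    if missing:
        raise KeyError(f"dyad table lacks columns: {sorted(missing)}")


def assign_focal_roles(dyads: pd.DataFrame, tie_break: str = "war_id",
                       measures=MEASURES,
                       rpd_kind: str = "bounded") -> pd.DataFrame:
    """Alternate the winner between focal and opponent down the duration order.

    Contests are sorted by ascending ``duration_days`` (ties broken by the
    ``tie_break`` column, ascending); at odd 1-based ranks the winner is the
    focal side, at even ranks the opponent.  For an even number of contests
    the focal side therefore wins exactly half.  Adds ``focal_state,
    opponent_state, outcome`` (1 when the focal side won) and a signed
    ``rpd_<m>`` for each measure, computed focal vs opponent.  Entirely
    deterministic.
    """
    _require_dyad_columns(dyads)
    if dyads.empty:
        out = dyads.copy()
        for c in ("focal_state", "opponent_state", "outcome"):
            out[c] = pd.Series(dtype=float)
        return out
    if tie_break not in dyads.columns:
        raise KeyError(f"tie-break column {tie_break!r} absent")
    out = dyads.sort_values(["duration_days", tie_break],
                            kind="mergesort").reset_index(drop=True)
    rank = np.arange(1, len(out) + 1)
    winner_focal = rank % 2 == 1
    out["focal_state"] = np.where(winner_focal, out["winner_state"],
                                  out["loser_state"])
    out["opponent_state"] = np.where(winner_focal, out["loser_state"],
                                     out["winner_state"])
    out["outcome"] = winner_focal.astype(int)
    for m in measures:
        wcol, lcol = f"winner_{m}", f"loser_{m}"
        if wcol not in out.columns or lcol not in out.columns:
            continue
        w = out[wcol].to_numpy(float)
        l = out[lcol].to_numpy(float)
        p_f = np.where(winner_focal, w, l)
        p_o = np.where(winner_focal, l, w)
        ok = np.isfinite(p_f) & np.isfinite(p_o) & ((p_f + p_o) > 0)
        rpd = np.full(len(out), np.nan)
        if ok.any():
            rpd[ok] = relative_power_difference(p_f[ok], p_o[ok],
                                                kind=rpd_kind)
        out[f"rpd_{m}"] = rpd
    return out


def balance_check(assigned: pd.DataFrame) -> dict:
    """Sanity report on the focal/opponent assignment.

    Counts wins per role and compares the mean log10 duration of contests
    won by each role with a Welch two-sample t test.  A role with zero wins
    is flagged, not raised.
    """
    if "outcome" not in assigned.columns:
        raise KeyError("run assign_focal_roles first")
    focal = assigned[assigned["outcome"] == 1]
    oppo = assigned[assigned["outcome"] == 0]
    report = {
        "n": int(len(assigned)),
        "focal_wins": int(len(focal)),
        "opponent_wins": int(len(oppo)),
        "imbalanced": bool(len(focal) == 0 or len(oppo) == 0),
    }
    if len(focal) and len(oppo):
        lf = np.log10(focal["duration_days"].to_numpy(float))
        lo = np.log10(oppo["duration_days"].to_numpy(float))
        report["mean_log10_duration_focal_wins"] = float(lf.mean())
        report["mean_log10_duration_opponent_wins"] = float(lo.mean())
        report["mean_duration_focal_wins"] = float(
            focal["duration_days"].mean())
        report["mean_duration_opponent_wins"] = float(
            oppo["duration_days"].mean())
        if len(lf) > 1 and len(lo) > 1 and (lf.std() > 0 or lo.std() > 0):
            t, p = stats.ttest_ind(lf, lo, equal_var=False)
            report["welch_t"] = float(t)
            report["welch_p"] = float(p)
        else:
            report["welch_t"] = np.nan
            report["welch_p"] = np.nan
    return report


def build_duration_design(dyads: pd.DataFrame, measure: str,
                          rpd_kind: str = "bounded",
                          log_powers: bool = True):
    """Duration-design rows for one power measure.

    Returns ``(design, n_dropped)``: one row per dyad with both sides'
    measure present, carrying ``log10_duration``, the three predictors
    (winner power, loser power, winner-vs-loser RPD) and the two identity
    columns used as crossed random intercepts.  Dyads missing the measure
    on either side are omitted and counted.

    With ``log_powers`` (the default) the two absolute-power predictors
    enter on the log10 scale, the usual treatment for right-skewed size
    and capability measures; the relative-power contrast is computed from
    the raw values either way, and the slope-sign diagnostics downstream
    are unaffected by the monotone transform.  Rows where a side's measure
    is zero cannot be log-transformed and are dropped with the missing
    ones.
    """
    _require_dyad_columns(dyads)
    wcol, lcol = f"winner_{measure}", f"loser_{measure}"
    if wcol not in dyads.columns or lcol not in dyads.columns:
        raise KeyError(f"measure {measure!r} absent from the dyad table")
    if (dyads["duration_days"] < 1).any():
        raise ValueError("duration_days < 1 violates the dyad contract")
    w = dyads[wcol].to_numpy(float)
    l = dyads[lcol].to_numpy(float)
    keep = np.isfinite(w) & np.isfinite(l) & ((w + l) > 0)
    if log_powers:
        keep &= (w > 0) & (l > 0)
    sub = dyads.loc[keep]
    wk, lk = w[keep], l[keep]
    design = pd.DataFrame({
        "war_id": sub["war_id"].to_numpy(),
        "log10_duration": np.log10(sub["duration_days"].to_numpy(float)),
        "winner_power": np.log10(wk) if log_powers else wk,
        "loser_power": np.log10(lk) if log_powers else lk,
        "relative_power": relative_power_difference(wk, lk, kind=rpd_kind),
        "winner_state": sub["winner_state"].to_numpy(),
        "loser_state": sub["loser_state"].to_numpy(),
    })
    return design, int((~keep).sum())


def standardize_column(frame: pd.DataFrame, column: str,
                       suffix: str = "_std"):
    """Z-standardize a column in place; returns (mean, sd) used.

    Slopes fitted on the standardized column relate to raw-scale slopes by
    the factor 1/sd; test statistics are invariant to the rescaling.
    """
    x = frame[column].to_numpy(float)
    mu = float(np.nanmean(x))
    sd = float(np.nanstd(x, ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"column {column!r} is constant; cannot "
                         "standardize")
    frame[column + suffix] = (x - mu) / sd
    return mu, sd
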