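"""Synthetic dyadic-contest generator under explicit assessment mechanisms.

Generates contest tables with the structure of the interstate-war data the
pipeline targets: a pool of states whose identities repeat across contests,
five positive, mutually correlated power measures per side, a winner and a
loser, and a duration in whole days.  Outcome and duration are produced by
one of four generative modes:

WOA (war of attrition / self-assessment)
    Each side persists for ``T_k = a * R_k**b * eps_k`` (eps log-normal);
    the side with the smaller persistence gives up, and the contest lasts
    ``min(T_i, T_j)``.  No information flows between sides: duration rises
    with both sides' RHP, most strongly the loser's.

SAM (sequential assessment / mutual assessment)
    The stronger side wins with probability ``Phi(|RPD| / s)`` and duration
    is ``a * exp(-|RPD| / s) * eps``: evenly matched opponents take longest
    to resolve, and at fixed loser RHP a stronger winner shortens the
    contest.

CAM (cumulative assessment)
    As WOA, but each side's give-up time is eroded by the damage its
    opponent inflicts: ``T_k = a * R_k**b / (1 + d * R_opp) * eps_k``.
    Duration rises with loser RHP and falls with winner RHP without any
    information exchange; ``d = 0`` recovers WOA exactly.

NULL
    Fair-coin winner, duration independent of all powers — the diagnostic's
    false-positive control.

RHP is log-normal: each state carries a persistent base level
(``rhp_sigma`` between states) and each war draws the state's RHP around
that base (``rhp_within_sd`` between wars within a state), the way national
capabilities drift between a state's wars.  The five measures load on the
contest-level log-RHP with independent log-normal noise, so every measure
is a true victory correlate of tunable strength and the measures are
positively correlated with each other, as capability data are.  One RNG
stream per dataset is split per contest by counter, so results for contest
``i`` do not depend on ``n_contests``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .prep import MEASURES, relative_power_difference

__all__ = ["SimulationConfig", "draw_contest", "simulate_dataset",
           "emit_cow_files", "recovery_experiment"]

# Measure loadings on log-RHP and per-measure log-scale noise: all five are
# genuine RHP correlates, with differing strength, and mutually correlated.
_DEFAULT_LOADINGS = {
    "pec": 0.8, "milper": 0.9, "tpop": 0.7, "upop": 0.7, "cinc": 1.0,
}
# Multiplicative scale per measure, chosen for plausible magnitudes
# (thousands of coal-ton equivalents, thousands of troops/people).
_MEASURE_SCALE = {"pec": 500.0, "milper": 100.0, "tpop": 5000.0,
                  "upop": 1000.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic contest dataset.

    Defaults mirror the scale of the interstate-war data the pipeline
    emulates: 44 contests drawn from a pool of 30 states (so identities
    repeat), a median contest of ~100 days under evenly matched sides, and
    moderate stochasticity in persistence.
    """

    mode: str = "WOA"              # WOA | SAM | CAM | NULL
    n_contests: int = 44
    n_states: int = 30
    rhp_mu: float = 0.0            # log-RHP location
    rhp_sigma: float = 1.0         # between-state log-RHP scale
    rhp_within_sd: float = 0.6     # between-war within-state log-RHP scale
    measure_loadings: dict = field(
        default_factory=lambda: dict(_DEFAULT_LOADINGS))
    measure_noise_sd: float = 0.3
    persistence_exponent: float = 1.0   # b: RHP -> endurance elasticity
    sampling_error: float = 0.25        # s: SAM assessment noise
    damage_rate: float = 0.5            # d: CAM cost infliction
    baseline_scale: float = 100.0       # a: days scaling
    noise_sd: float = 0.4               # multiplicative log-normal noise
    whole_days: bool = True
    first_year: int = 1823
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("WOA", "SAM", "CAM", "NULL"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_contests < 1:
            raise ValueError("n_contests must be >= 1")
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        for name in ("rhp_sigma", "sampling_error", "baseline_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("measure_noise_sd", "noise_sd", "damage_rate",
                     "persistence_exponent", "rhp_within_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _state_pool(config: SimulationConfig):
    """Persistent per-state base log-RHP and the pool capability total."""
    rng = np.random.default_rng([config.seed, 0xA11CE])
    base_log_rhp = config.rhp_mu + config.rhp_sigma * rng.standard_normal(
        config.n_states)
    # denominator for the composite-index share, from the base levels
    pool_total = float(np.exp(base_log_rhp).sum())
    return base_log_rhp, pool_total


def _side_measures(config: SimulationConfig, log_rhp, pool_total, rng):
    """Five measures for one side at its year of entry."""
    out = {}
    for m in MEASURES:
        lam = config.measure_loadings.get(m, 1.0)
        raw = math.exp(lam * log_rhp
                       + config.measure_noise_sd * rng.standard_normal())
        if m == "cinc":
            out[m] = min(raw / pool_total, 1.0)
        else:
            out[m] = _MEASURE_SCALE[m] * raw
    return out


def draw_contest(config: SimulationConfig, state_pair, rhp_pair,
                 contest_index: int) -> dict:
    """Generate outcome and duration for one contest.

    ``state_pair`` are two distinct state codes and ``rhp_pair`` their
    positive RHP values.  Deterministic given config.seed and the contest
    index; identical random draws feed every mode, so CAM with d = 0
    reproduces WOA contest by contest.
    """
    s_i, s_j = state_pair
    r_i, r_j = float(rhp_pair[0]), float(rhp_pair[1])
    if s_i == s_j:
        raise ValueError("a contest needs two distinct states")
    if r_i <= 0 or r_j <= 0:
        raise ValueError("RHP must be positive")
    rng = np.random.default_rng([config.seed, 0xC0117E57, contest_index])
    eps_i, eps_j = np.exp(config.noise_sd * rng.standard_normal(2))
    u = rng.random()
    eps_d = math.exp(config.noise_sd * rng.standard_normal())

    a, b = config.baseline_scale, config.persistence_exponent
    mode = config.mode
    if mode in ("WOA", "CAM"):
        d = config.damage_rate if mode == "CAM" else 0.0
        t_i = a * r_i ** b / (1.0 + d * r_j) * eps_i
        t_j = a * r_j ** b / (1.0 + d * r_i) * eps_j
        i_wins = t_i > t_j
        duration = min(t_i, t_j)
    elif mode == "SAM":
        rpd = relative_power_difference(r_i, r_j)
        p_strong = stats.norm.cdf(abs(rpd) / config.sampling_error)
        strong_is_i = r_i >= r_j
        strong_wins = u < p_strong
        i_wins = strong_is_i == strong_wins
        duration = a * math.exp(-abs(rpd) / config.sampling_error) * eps_d
    else:  # NULL
        i_wins = u < 0.5
        duration = a * eps_d
    if config.whole_days:
        duration = max(1, math.ceil(duration))
    winner, loser = (s_i, s_j) if i_wins else (s_j, s_i)
    return {"winner_state": int(winner), "loser_state": int(loser),
            "duration_days": duration}


def simulate_dataset(config: SimulationConfig):
    """Draw a full contest table.

    Returns ``(dyads, states)``: the dyad table in the layout
    :mod:`contestkit.prep` consumes, plus a per-state table of codes and
    measures (used by the file emitter).  Byte-identical output for
    identical config.
    """
    base_log_rhp, pool_total = _state_pool(config)
    codes = np.arange(2, 2 + config.n_states)  # COW-style codes start at 2
    rows = []
    for i in range(config.n_contests):
        pair_rng = np.random.default_rng([config.seed, 0x9A185, i])
        idx = pair_rng.choice(config.n_states, size=2, replace=False)
        # contest-level RHP: state base plus between-war drift
        log_rhp = (base_log_rhp[idx]
                   + config.rhp_within_sd * pair_rng.standard_normal(2))
        rhp = np.exp(log_rhp)
        contest = draw_contest(config, codes[idx], rhp, i)
        year = config.first_year + i
        row = {"war_id": i + 1, **contest,
               "winner_entry_year": year, "loser_entry_year": year}
        widx = 0 if contest["winner_state"] == codes[idx[0]] else 1
        lidx = 1 - widx
        for side_idx, role in ((widx, "winner"), (lidx, "loser")):
            # one sub-stream per side keeps winner/loser draws decoupled
            side_rng = np.random.default_rng(
                [config.seed, 0x3EA5, i, int(idx[side_idx])])
            vals = _side_measures(config, float(log_rhp[side_idx]),
                                  pool_total, side_rng)
            for m in MEASURES:
                row[f"{role}_{m}"] = float(vals[m])
        rows.append(row)
    dyads = pd.DataFrame(rows)
    states = pd.DataFrame({"state_code": codes,
                           "base_rhp": np.exp(base_log_rhp)})
    return dyads, states


def emit_cow_files(dyads: pd.DataFrame, states: pd.DataFrame,
                   war_path, caps_path):
    """Write the dataset as a war/capability file pair in the COW dialect.

    War start dates are placed at 1 January of each side's entry year and
    the end date is ``duration_days - 1`` days later, so re-ingestion under
    the inclusive day-count convention reproduces the duration exactly.
    Capabilities are emitted per (state, entry year); absent measures
    become the dialect's -9 sentinel.
    """
    war_rows, cap_keys = [], {}
    for _, r in dyads.iterrows():
        start = pd.Timestamp(int(r["winner_entry_year"]), 1, 1)
        end = start + pd.Timedelta(days=int(r["duration_days"]) - 1)
        for role, outcome in (("winner", 1), ("loser", 2)):
            code = int(r[f"{role}_state"])
            war_rows.append({
                "WarNum": int(r["war_id"]),
                "WarName": f"Synthetic War {int(r['war_id'])}",
                "ccode": code,
                "StateName": f"State {code}",
                "Side": 1 if role == "winner" else 2,
                "Outcome": outcome,
                "StartYear1": start.year, "StartMonth1": start.month,
                "StartDay1": start.day,
                "EndYear1": end.year, "EndMonth1": end.month,
                "EndDay1": end.day,
            })
            year = int(r[f"{role}_entry_year"])
            vals = {m: r[f"{role}_{m}"] for m in MEASURES}
            cap_keys[(code, year)] = vals
    pd.DataFrame(war_rows).to_csv(war_path, index=False)

    cap_rows = []
    for (code, year), vals in sorted(cap_keys.items()):
        row = {"ccode": code, "stateabb": f"S{code:03d}", "year": year}
        for m in MEASURES:
            v = vals[m]
            row[m] = -9 if (v is None or not np.isfinite(v)) else repr(
                float(v))
        cap_rows.append(row)
    pd.DataFrame(cap_rows).to_csv(caps_path, index=False)


def recovery_experiment(config: SimulationConfig, n_replicates: int,
                        alpha: float = 0.05, trend_alpha: float = 0.10,
                        measures=MEASURES, key_measure: str = "cinc",
                        control: dict | None = None) -> dict:
    """Replicate simulate -> two-step diagnosis and tally the verdicts.

    Each replicate re-seeds the generator deterministically from
    ``config.seed`` and the replicate index, simulates a dataset, runs the
    full two-step analysis and records the verdict for every screened
    measure.  The replicate-level verdict is the one for ``key_measure``
    (the composite index by default, mirroring the primary analysis).
    Replicates whose pipeline raises are excluded and counted.
    """
    from .diagnostic import run_two_step  # deferred: circular import

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    verdict_counts: dict = {}
    measure_verdicts = {m: {} for m in measures}
    screen_pass = {m: 0 for m in measures}
    n_failed = 0
    for rep in range(n_replicates):
        rep_config = replace(
            config, seed=(config.seed * 100_003 + rep) % (2**31 - 1))
        try:
            dyads, _ = simulate_dataset(rep_config)
            report = run_two_step(dyads, measures=measures, alpha=alpha,
                                  trend_alpha=trend_alpha, control=control,
                                  duration_measures=(key_measure,))
        except Exception:
            n_failed += 1
            continue
        for m in measures:
            sr = report["screen"][m]
            if sr.is_rhp_correlate:
                screen_pass[m] += 1
            if m in report["verdicts"]:
                cat = report["verdicts"][m].category
                measure_verdicts[m][cat] = \
                    measure_verdicts[m].get(cat, 0) + 1
        key = report["verdicts"].get(key_measure)
        cat = key.category if key is not None else "unscreened"
        verdict_counts[cat] = verdict_counts.get(cat, 0) + 1
    n_ok = n_replicates - n_failed
    return {
        "mode": config.mode,
        "n_replicates": n_replicates,
        "n_completed": n_ok,
        "n_failed": n_failed,
        "key_measure": key_measure,
        "verdict_counts": verdict_counts,
        "verdict_rates": {k: v / n_ok for k, v in verdict_counts.items()}
        if n_ok else {},
        "screen_pass_rates": {m: screen_pass[m] / n_ok for m in measures}
        if n_ok else {},
        "measure_verdicts": measure_verdicts,
    }
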