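"""Readers for Correlates-of-War-dialect tables and dyad assembly.

The inter-state war file has one row per (war, participant) with outcome
codes and entry/exit dates; the national-material-capabilities file has
one row per (state, year) with the five power measures (PEC, MILPER, TPOP,
UPOP, CINC).  Both are plain CSV with a header row; column names, outcome
codes and missing-value sentinels are a configurable *dialect*, defaulting
to the v4.0 conventions, so other dataset versions map without code edits.

Dyad assembly applies the exclusion filters of the analysis: only wars
between exactly two individual states with exactly one coded winner and
one coded loser are kept; stalemates, wars that transformed into other
wars, and coalition wars are excluded with the reason recorded.  Duration
is counted inclusively ((end - start) + 1 days, so a one-day war has
duration 1) and each side carries its capabilities for the year in which
it entered the war.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .prep import MEASURES

__all__ = [
    "WarDialect",
    "CapabilityDialect",
    "read_war_table",
    "read_capabilities_table",
    "build_dyads",
    "DEFAULT_WAR_DIALECT",
    "DEFAULT_CAP_DIALECT",
]

OUTCOME_CATEGORIES = ("won", "lost", "stalemate", "transformed", "other")


@dataclass(frozen=True)
class WarDialect:
    """Column mapping and outcome-code table for a war file."""

    war_id: str = "WarNum"
    war_name: str = "WarName"
    state_code: str = "ccode"
    state_name: str = "StateName"
    side: str = "Side"
    outcome: str = "Outcome"
    start_year: str = "StartYear1"
    start_month: str = "StartMonth1"
    start_day: str = "StartDay1"
    end_year: str = "EndYear1"
    end_month: str = "EndMonth1"
    end_day: str = "EndDay1"
    # v4 outcome codes: 1 winner, 2 loser, 3 compromise, 4 transformed,
    # 5 ongoing, 6 stalemate, 7 continues below war level, 8 changed sides
    outcome_codes: dict = field(default_factory=lambda: {
        1: "won", 2: "lost", 3: "other", 4: "transformed",
        5: "other", 6: "stalemate", 7: "other", 8: "other"})
    sentinel: int = -9

    @property
    def required_columns(self):
        return (self.war_id, self.state_code, self.outcome,
                self.start_year, self.start_month, self.start_day,
                self.end_year, self.end_month, self.end_day)


@dataclass(frozen=True)
class CapabilityDialect:
    state_code: str = "ccode"
    year: str = "year"
    measures: dict = field(default_factory=lambda: {m: m for m in MEASURES})
    sentinel: float = -9.0

    @property
    def required_columns(self):
        return (self.state_code, self.year, *self.measures.values())


DEFAULT_WAR_DIALECT = WarDialect()
DEFAULT_CAP_DIALECT = CapabilityDialect()


class DialectError(ValueError):
    """A file does not match its configured dialect."""


def _check_columns(frame: pd.DataFrame, required, path):
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DialectError(
            f"{path}: missing mandatory column(s) {missing}")


def _parse_date(row, dialect, prefix, sentinel):
    y = int(row[getattr(dialect, f"{prefix}_year")])
    mth = int(row[getattr(dialect, f"{prefix}_month")])
    d = int(row[getattr(dialect, f"{prefix}_day")])
    if y == sentinel or mth == sentinel or d == sentinel:
        raise ValueError(f"{prefix} date has a missing component")
    return date(y, mth, d)


def read_war_table(path, dialect: WarDialect = DEFAULT_WAR_DIALECT):
    """Parse a war-participant file.

    Returns ``(records, load_report)``: a DataFrame with one row per
    (war, participant) and columns ``war_id, war_name, state_code, side,
    outcome, entry_date, exit_date``, plus a list of row-level problems
    (1-based data row number and message).  Rows with unmapped outcome
    codes or unparseable dates go to the report and are dropped.
    """
    raw = pd.read_csv(path, float_precision="round_trip")
    _check_columns(raw, dialect.required_columns, path)
    records, report = [], []
    for i, row in raw.iterrows():
        rownum = int(i) + 1
        try:
            code = int(row[dialect.outcome])
            outcome = dialect.outcome_codes.get(code)
            if outcome is None:
                report.append((rownum,
                               f"outcome code {code} outside the dialect "
                               f"enumeration"))
                continue
            entry = _parse_date(row, dialect, "start", dialect.sentinel)
            exit_ = _parse_date(row, dialect, "end", dialect.sentinel)
            if entry > exit_:
                report.append((rownum, "entry date after exit date"))
                continue
        except (ValueError, TypeError) as exc:
            report.append((rownum, f"unparseable row: {exc}"))
            continue
        records.append({
            "war_id": int(row[dialect.war_id]),
            "war_name": str(row.get(dialect.war_name, "")),
            "state_code": int(row[dialect.state_code]),
            "side": int(row[dialect.side])
            if dialect.side in raw.columns else 0,
            "outcome": outcome,
            "entry_date": entry,
            "exit_date": exit_,
        })
    cols = ["war_id", "war_name", "state_code", "side", "outcome",
            "entry_date", "exit_date"]
    return pd.DataFrame(records, columns=cols), report


def read_capabilities_table(path,
                            dialect: CapabilityDialect = DEFAULT_CAP_DIALECT):
    """Parse a state-year capability file into a (state, year) lookup.

    Returns ``(caps, load_report)``: a DataFrame indexed by
    ``(state_code, year)`` with the five measures, sentinel values
    normalized to NaN (explicitly absent).  Duplicate keys are a hard
    error; negative non-sentinel values go to the report and become NaN.
    """
    raw = pd.read_csv(path, float_precision="round_trip")
    _check_columns(raw, dialect.required_columns, path)
    key = [dialect.state_code, dialect.year]
    dup = raw.duplicated(subset=key, keep=False)
    if dup.any():
        keys = raw.loc[dup, key].drop_duplicates().to_records(index=False)
        raise DialectError(
            f"{path}: duplicate (state, year) key(s): {list(keys)}")
    report = []
    out = pd.DataFrame({
        "state_code": raw[dialect.state_code].astype(int),
        "year": raw[dialect.year].astype(int),
    })
    for name, col in dialect.measures.items():
        vals = pd.to_numeric(raw[col], errors="coerce").astype(float)
        sentinel_mask = vals == dialect.sentinel
        bad = vals.notna() & (vals < 0) & ~sentinel_mask
        for i in raw.index[bad]:
            report.append((int(i) + 1,
                           f"negative non-sentinel value in {col}"))
        vals[sentinel_mask | bad] = np.nan
        if name == "cinc" and (vals > 1).any():
            for i in raw.index[vals > 1]:
                report.append((int(i) + 1, "cinc outside [0, 1]"))
            vals[vals > 1] = np.nan
        out[name] = vals
    return out.set_index(["state_code", "year"]), report


def lookup_capability(caps: pd.DataFrame, state_code: int, year: int):
    """Measures for one (state, year); absent keys give all-NaN, no raise."""
    try:
        row = caps.loc[(state_code, year)]
        return {m: float(row[m]) for m in MEASURES}
    except KeyError:
        return {m: np.nan for m in MEASURES}


def build_dyads(wars: pd.DataFrame, caps: pd.DataFrame,
                missing_policy: str = "per-measure"):
    """Assemble winner/loser dyads from participant records.

    A dyad is emitted iff a war involved exactly two distinct states with
    exactly one coded winner and one coded loser.  War dates are the
    earliest entry and latest exit over participants; duration is the
    inclusive day count.  Each side carries its capabilities for its year
    of entry (a state with several entry dates uses the earliest).

    ``missing_policy``: "per-measure" (default) keeps a dyad with absent
    measures marked NaN, to be dropped only from analyses of the affected
    measure; "drop" excludes the dyad when any measure is absent.

    Returns ``(dyads, exclusions)``; every input war appears in exactly
    one of the two tables.
    """
    if missing_policy not in ("per-measure", "drop"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    dyad_rows, excl_rows = [], []
    for war_id, grp in wars.groupby("war_id", sort=True):
        name = grp["war_name"].iloc[0]

        def exclude(reason):
            excl_rows.append({"war_id": war_id, "war_name": name,
                              "reason": reason})

        states = grp["state_code"].unique()
        if len(states) != 2:
            exclude("coalition" if len(states) > 2 else "single-state")
            continue
        if set(grp["outcome"]) & {"stalemate", "transformed", "other"}:
            exclude("no-clear-outcome")
            continue
        winners = [s for s in states if (grp.loc[grp.state_code == s,
                                                 "outcome"] == "won").all()]
        losers = [s for s in states if (grp.loc[grp.state_code == s,
                                                "outcome"] == "lost").all()]
        if len(winners) != 1 or len(losers) != 1:
            exclude("inconsistent outcome")
            continue
        winner, loser = winners[0], losers[0]
        start = grp["entry_date"].min()
        end = grp["exit_date"].max()
        duration = (end - start).days + 1
        row = {"war_id": war_id, "war_name": name,
               "winner_state": int(winner), "loser_state": int(loser),
               "duration_days": int(duration)}
        any_missing = False
        for role, state in (("winner", winner), ("loser", loser)):
            entry_year = grp.loc[grp.state_code == state,
                                 "entry_date"].min().year
            row[f"{role}_entry_year"] = int(entry_year)
            vals = lookup_capability(caps, int(state), int(entry_year))
            for m in MEASURES:
                row[f"{role}_{m}"] = vals[m]
                if not np.isfinite(vals[m]):
                    any_missing = True
        if any_missing and missing_policy == "drop":
            exclude("missing-capability")
            continue
        dyad_rows.append(row)

    dyad_cols = ["war_id", "war_name", "winner_state", "loser_state",
                 "duration_days", "winner_entry_year", "loser_entry_year"]
    dyad_cols += [f"{role}_{m}" for role in ("winner", "loser")
                  for m in MEASURES]
    dyads = pd.DataFrame(dyad_rows, columns=dyad_cols)
    exclusions = pd.DataFrame(excl_rows,
                              columns=["war_id", "war_name", "reason"])
    return dyads, exclusions
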