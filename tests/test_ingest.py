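import numpy as np
import pandas as pd
import pytest

from contestkit.ingest import (DEFAULT_CAP_DIALECT, DEFAULT_WAR_DIALECT,
                               DialectError, build_dyads,
                               lookup_capability, read_capabilities_table,
                               read_war_table)
from contestkit.prep import MEASURES
from contestkit.simulate import SimulationConfig, emit_cow_files, \
    simulate_dataset


def _war_row(war, ccode, outcome, start=(1900, 1, 1), end=(1900, 1, 10),
             side=1, name="Test War"):
    return {"WarNum": war, "WarName": name, "ccode": ccode,
            "StateName": f"State {ccode}", "Side": side,
            "Outcome": outcome,
            "StartYear1": start[0], "StartMonth1": start[1],
            "StartDay1": start[2], "EndYear1": end[0],
            "EndMonth1": end[1], "EndDay1": end[2]}


def _cap_row(ccode, year, **vals):
    row = {"ccode": ccode, "stateabb": f"S{ccode}", "year": year}
    for m in MEASURES:
        row[m] = vals.get(m, 1.0 if m != "cinc" else 0.01)
    return row


def _write(tmp_path, name, rows):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


class TestReadWarTable:
    def test_row_count_and_grouping(self, tmp_path):
        rows = [_war_row(1, c, o) for c, o in ((2, 1), (3, 2), (4, 2))]
        rows += [_war_row(2, c, o) for c, o in ((5, 1), (6, 2), (7, 2))]
        recs, report = read_war_table(_write(tmp_path, "w.csv", rows))
        assert len(recs) == 6
        assert recs["war_id"].nunique() == 2
        assert not report

    def test_unknown_outcome_code_goes_to_report(self, tmp_path):
        rows = [_war_row(1, 2, 1), _war_row(1, 3, 99)]
        recs, report = read_war_table(_write(tmp_path, "w.csv", rows))
        assert len(recs) == 1
        assert len(report) == 1 and "99" in report[0][1]

    def test_missing_column_is_configuration_error(self, tmp_path):
        rows = [_war_row(1, 2, 1)]
        for r in rows:
            del r["Outcome"]
        with pytest.raises(DialectError, match="Outcome"):
            read_war_table(_write(tmp_path, "w.csv", rows))

    def test_bad_date_collected_not_raised(self, tmp_path):
        rows = [_war_row(1, 2, 1), _war_row(1, 3, 2, start=(1900, 13, 1))]
        recs, report = read_war_table(_write(tmp_path, "w.csv", rows))
        assert len(recs) == 1
        assert report and report[0][0] == 2  # 1-based data row number


class TestReadCapabilities:
    def test_identity_lookup(self, tmp_path):
        path = _write(tmp_path, "c.csv",
                      [_cap_row(2, 1900, pec=3.5, cinc=0.2)])
        caps, report = read_capabilities_table(path)
        vals = lookup_capability(caps, 2, 1900)
        assert vals["pec"] == 3.5
        assert vals["cinc"] == 0.2
        assert not report

    def test_sentinel_normalized_to_absent(self, tmp_path):
        path = _write(tmp_path, "c.csv", [_cap_row(2, 1900, upop=-9)])
        caps, _ = read_capabilities_table(path)
        vals = lookup_capability(caps, 2, 1900)
        assert np.isnan(vals["upop"])
        assert vals["milper"] == 1.0  # other measures retained

    def test_absent_key_returns_absent_not_raises(self, tmp_path):
        path = _write(tmp_path, "c.csv", [_cap_row(2, 1900)])
        caps, _ = read_capabilities_table(path)
        assert all(np.isnan(v)
                   for v in lookup_capability(caps, 999, 1901).values())

    def test_duplicate_key_is_hard_error(self, tmp_path):
        path = _write(tmp_path, "c.csv",
                      [_cap_row(2, 1900), _cap_row(2, 1900)])
        with pytest.raises(DialectError, match="duplicate"):
            read_capabilities_table(path)

    def test_negative_non_sentinel_reported(self, tmp_path):
        path = _write(tmp_path, "c.csv", [_cap_row(2, 1900, milper=-3)])
        caps, report = read_capabilities_table(path)
        assert report and "milper" in report[0][1]
        assert np.isnan(lookup_capability(caps, 2, 1900)["milper"])


class TestBuildDyads:
    def _standard_input(self, tmp_path):
        wars = [
            # war 1: clean dyad
            _war_row(1, 2, 1), _war_row(1, 3, 2, side=2),
            # war 2: three-state coalition
            _war_row(2, 4, 1), _war_row(2, 5, 1), _war_row(2, 6, 2),
            # war 3: dyadic stalemate
            _war_row(3, 7, 6), _war_row(3, 8, 6),
        ]
        caps = [_cap_row(c, 1900) for c in range(2, 9)]
        recs, _ = read_war_table(_write(tmp_path, "w.csv", wars))
        cap_tbl, _ = read_capabilities_table(_write(tmp_path, "c.csv",
                                                    caps))
        return recs, cap_tbl

    def test_filters_and_reasons(self, tmp_path):
        recs, caps = self._standard_input(tmp_path)
        dyads, excl = build_dyads(recs, caps)
        assert len(dyads) == 1
        assert dyads.iloc[0]["winner_state"] == 2
        reasons = dict(zip(excl["war_id"], excl["reason"]))
        assert reasons == {2: "coalition", 3: "no-clear-outcome"}
        # partition invariant
        assert len(dyads) + len(excl) == recs["war_id"].nunique()

    def test_inclusive_day_count(self, tmp_path):
        recs, caps = self._standard_input(tmp_path)
        dyads, _ = build_dyads(recs, caps)
        # entry 1900-01-01, exit 1900-01-10 -> 10 calendar days inclusive
        assert dyads.iloc[0]["duration_days"] == 10

    def test_capabilities_at_year_of_entry(self, tmp_path):
        wars = [_war_row(1, 2, 1, start=(1914, 7, 28), end=(1915, 3, 1)),
                _war_row(1, 3, 2, start=(1915, 1, 5), end=(1915, 3, 1))]
        caps = [_cap_row(2, 1914, pec=100.0), _cap_row(2, 1915, pec=1.0),
                _cap_row(3, 1914, pec=2.0), _cap_row(3, 1915, pec=200.0)]
        recs, _ = read_war_table(_write(tmp_path, "w.csv", wars))
        cap_tbl, _ = read_capabilities_table(_write(tmp_path, "c.csv",
                                                    caps))
        dyads, _ = build_dyads(recs, cap_tbl)
        assert dyads.iloc[0]["winner_pec"] == 100.0  # entered 1914
        assert dyads.iloc[0]["loser_pec"] == 200.0   # entered 1915

    def test_two_winners_is_inconsistent(self, tmp_path):
        wars = [_war_row(1, 2, 1), _war_row(1, 3, 1)]
        caps = [_cap_row(2, 1900), _cap_row(3, 1900)]
        recs, _ = read_war_table(_write(tmp_path, "w.csv", wars))
        cap_tbl, _ = read_capabilities_table(_write(tmp_path, "c.csv",
                                                    caps))
        dyads, excl = build_dyads(recs, cap_tbl)
        assert len(dyads) == 0
        assert excl.iloc[0]["reason"] == "inconsistent outcome"

    def test_missing_capability_policies(self, tmp_path):
        wars = [_war_row(1, 2, 1), _war_row(1, 3, 2)]
        caps = [_cap_row(2, 1900), _cap_row(3, 1900, upop=-9)]
        recs, _ = read_war_table(_write(tmp_path, "w.csv", wars))
        cap_tbl, _ = read_capabilities_table(_write(tmp_path, "c.csv",
                                                    caps))
        kept, _ = build_dyads(recs, cap_tbl, missing_policy="per-measure")
        assert len(kept) == 1 and np.isnan(kept.iloc[0]["loser_upop"])
        dropped, excl = build_dyads(recs, cap_tbl, missing_policy="drop")
        assert len(dropped) == 0
        assert excl.iloc[0]["reason"] == "missing-capability"


class TestRoundTrip:
    def test_simulator_files_reingest_exactly(self, tmp_path):
        """COW-dialect files written by the simulator reproduce the
        in-memory dyad table exactly: identities, durations, powers."""
        cfg = SimulationConfig(mode="WOA", n_contests=30, seed=99)
        dyads, states = simulate_dataset(cfg)
        war_path = tmp_path / "wars.csv"
        cap_path = tmp_path / "caps.csv"
        emit_cow_files(dyads, states, war_path, cap_path)
        recs, war_rep = read_war_table(war_path)
        caps, cap_rep = read_capabilities_table(cap_path)
        assert not war_rep and not cap_rep
        round_tripped, excl = build_dyads(recs, caps)
        assert len(excl) == 0
        cols = ["war_id", "winner_state", "loser_state", "duration_days",
                "winner_entry_year", "loser_entry_year"]
        cols += [f"{r}_{m}" for r in ("winner", "loser") for m in MEASURES]
        pd.testing.assert_frame_equal(
            round_tripped[cols].reset_index(drop=True),
            dyads[cols].reset_index(drop=True), check_dtype=False)
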