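"""Baselines, hourly Welch tests, threshold tables and the warning rule."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import somrisk as sr
from somrisk import risk


def _constant_profile(mu, sigma, season="summer"):
    idx = pd.RangeIndex(1, 169, name="window_hour")
    mean = pd.DataFrame({v: np.full(168, mu[v]) for v in risk.RISK_VARIABLES},
                        index=idx)
    sd = pd.DataFrame({v: np.full(168, sigma[v]) for v in risk.RISK_VARIABLES},
                      index=idx)
    return sr.BaselineProfile(season, mean, sd, 10)


MU = {"AP": 1003.0, "T": 29.0, "WS": 2.0, "R": 0.2}
SIGMA = {"AP": 2.0, "T": 1.5, "WS": 0.5, "R": 0.3}


class TestBaselineProfiles:
    def test_constant_series_gives_zero_sd(self, quiet_params):
        series = sr.simulate_station(quiet_params, 40, date(2017, 6, 1),
                                     seed=0)
        profiles = sr.baseline_profiles({"S": series}, [], seed=0)
        p = profiles["summer"]
        assert p.n_windows >= 2
        assert np.allclose(p.sd["AP"], 0.0)
        assert np.allclose(p.mean["AP"], 1003.0)

    def test_windows_never_overlap_kill_windows(self):
        series = sr.simulate_station(sr.SUMMER, 40, date(2017, 6, 1), seed=1)
        events = [sr.KillEvent("E1", series.station_id, date(2017, 6, 20))]
        ends = sr.sample_baseline_windows(series, events, seed=2)
        kill_start = pd.Timestamp(date(2017, 6, 14))
        kill_end = pd.Timestamp(date(2017, 6, 20))
        for end in ends:
            start = end - pd.Timedelta(days=6)
            assert end < kill_start or start > kill_end

    def test_chosen_windows_do_not_overlap_each_other(self):
        series = sr.simulate_station(sr.SUMMER, 60, date(2017, 6, 1), seed=3)
        ends = sr.sample_baseline_windows(series, [], seed=4)
        ends = sorted(ends)
        assert all((b - a).days >= 7 for a, b in zip(ends, ends[1:]))

    def test_too_few_windows_errors(self):
        series = sr.simulate_station(sr.SUMMER, 8, date(2017, 6, 1), seed=5)
        events = [sr.KillEvent("E1", series.station_id, date(2017, 6, 8))]
        with pytest.raises(ValueError, match="fewer than 2"):
            sr.baseline_profiles({series.station_id: series}, events, seed=6)

    def test_parameter_recovery_at_depth(self):
        series = sr.simulate_station(sr.NON_SUMMER, 120, date(2017, 4, 1),
                                     seed=7)
        profiles = sr.baseline_profiles({"S": series}, [], seed=8)
        p = profiles["non_summer"]
        se = sr.NON_SUMMER.t_sd / np.sqrt(p.n_windows)
        # slot means average the diurnal cycle away when pooled over hours
        assert abs(p.mean["T"].mean() - sr.NON_SUMMER.t_mean) < 4 * se
        assert abs(p.sd["T"].mean() - sr.NON_SUMMER.t_sd) < 0.15 * 1.5 + 0.3


class TestHourlyTests:
    def _windows(self, rng, n, shift=0.0):
        return {v: shift * (v == "T") + rng.standard_normal((n, 168))
                for v in risk.RISK_VARIABLES}

    def test_identical_constants_give_p_one(self):
        kill = {v: np.ones((3, 168)) for v in risk.RISK_VARIABLES}
        base = {v: np.ones((5, 168)) for v in risk.RISK_VARIABLES}
        sig = sr.hourly_tests(kill, base)
        assert (sig.p.to_numpy() == 1.0).all()

    def test_distinct_constants_give_p_zero(self):
        kill = {v: np.full((3, 168), 2.0) for v in risk.RISK_VARIABLES}
        base = {v: np.ones((5, 168)) for v in risk.RISK_VARIABLES}
        sig = sr.hourly_tests(kill, base)
        assert (sig.p.to_numpy() == 0.0).all()

    def test_matches_scipy_welch_slotwise(self, rng):
        from scipy import stats
        kill = self._windows(rng, 6)
        base = self._windows(rng, 9)
        sig = sr.hourly_tests(kill, base)
        p = stats.ttest_ind(kill["AP"][:, 17], base["AP"][:, 17],
                            equal_var=False).pvalue
        assert np.isclose(sig.p["AP"].iloc[17], p)

    def test_shifted_variable_is_flagged(self, rng):
        kill = self._windows(rng, 11, shift=1.0)
        base = self._windows(rng, 30)
        sig = sr.hourly_tests(kill, base)
        assert sig.frac_significant["T"] > 0.5
        assert sig.frac_significant["AP"] < 0.2

    def test_too_few_windows_rejected(self, rng):
        kill = self._windows(rng, 1)
        base = self._windows(rng, 5)
        with pytest.raises(ValueError):
            sr.hourly_tests(kill, base)


class TestThresholdTable:
    def test_constant_baseline_closed_form(self):
        table = sr.threshold_table(_constant_profile(MU, SIGMA)).table
        for d in range(1, 8):
            assert np.isclose(table.loc[d, "AP_min_normal"], 1003.0)
            assert np.isclose(table.loc[d, "AP_min_minus1sd"], 1001.0)
            assert np.isclose(table.loc[d, "T_max_normal"], 29.0)
            assert np.isclose(table.loc[d, "T_max_plus1sd"], 30.5)
            assert np.isclose(table.loc[d, "WS_min_minus1sd"], 1.5)
            assert np.isclose(table.loc[d, "R_max_plus1sd"], 0.5)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_one_sd_bounds_bracket_normal_bounds(self, seed):
        rng = np.random.default_rng(seed)
        idx = pd.RangeIndex(1, 169, name="window_hour")
        mean = pd.DataFrame(
            {v: rng.normal(MU[v], 1.0, 168) for v in risk.RISK_VARIABLES},
            index=idx)
        sd = pd.DataFrame(
            {v: rng.uniform(0, 2.0, 168) for v in risk.RISK_VARIABLES},
            index=idx)
        table = sr.threshold_table(
            sr.BaselineProfile("summer", mean, sd, 5)).table
        assert (table["AP_min_minus1sd"] <= table["AP_min_normal"]).all()
        assert (table["WS_min_minus1sd"] <= table["WS_min_normal"]).all()
        assert (table["T_max_plus1sd"] >= table["T_max_normal"]).all()
        assert (table["R_max_plus1sd"] >= table["R_max_normal"]).all()

    def test_recovery_from_known_slot_parameters(self):
        from somrisk.experiments import threshold_recovery_error
        errors = threshold_recovery_error(seed=11)
        for v in risk.RISK_VARIABLES:
            assert errors[v] <= errors[f"{v}_tol"], v


class TestEvaluateWarnings:
    def _window(self, **overrides):
        base = {v: np.full(168, MU[v]) for v in risk.RISK_VARIABLES}
        base.update(overrides)
        return pd.DataFrame(base)

    def _table(self):
        return sr.threshold_table(_constant_profile(MU, SIGMA))

    def test_baseline_mean_window_is_quiet(self):
        states = sr.evaluate_warnings(self._window(), self._table())
        assert all(s.level == "none" and not s.crossed for s in states)

    def test_single_day_temperature_crossing(self):
        t = np.full(168, MU["T"])
        t[2 * 24 + 5] = MU["T"] + 2 * SIGMA["T"]  # day 3 only
        states = sr.evaluate_warnings(self._window(T=t), self._table())
        levels = {s.day: s.level for s in states}
        assert levels[3] == "warning"
        assert all(levels[d] == "none" for d in levels if d != 3)
        assert states[2].crossed == frozenset({"T"})

    def test_two_crossings_escalate_to_action(self):
        t = np.full(168, MU["T"]); t[10] = MU["T"] + 5
        ap = np.full(168, MU["AP"]); ap[15] = MU["AP"] - 5
        states = sr.evaluate_warnings(self._window(T=t, AP=ap), self._table())
        assert states[0].level == "action"
        assert states[0].crossed == frozenset({"T", "AP"})

    def test_warning_level_is_monotone_in_crossings(self):
        rank = {"none": 0, "warning": 1, "action": 2}
        t = np.full(168, MU["T"]); t[10] = MU["T"] + 5
        one = sr.evaluate_warnings(self._window(T=t), self._table())
        ws = np.full(168, MU["WS"]); ws[12] = 0.0
        two = sr.evaluate_warnings(self._window(T=t, WS=ws), self._table())
        for a, b in zip(one, two):
            assert rank[b.level] >= rank[a.level]
            assert a.crossed <= b.crossed

    def test_season_mismatch_rejected(self):
        with pytest.raises(ValueError, match="season"):
            sr.evaluate_warnings(self._window(), self._table(),
                                 season="non_summer")

    def test_injected_signature_triggers_action(self):
        from somrisk.experiments import warning_detection
        rate, quiet = warning_detection(seed=21, n_reps=10)
        assert rate >= 0.8
        assert quiet
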