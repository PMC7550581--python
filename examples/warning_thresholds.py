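"""Build warning thresholds from non-kill baselines and evaluate a window.

Seasonal baselines are per-hour means and SDs over 7-day windows with no
kill events; the threshold table takes the daily extremes of the mean and
the mean±1 SD envelope.  A variable crossing its ±1 SD bound is a warning
signal; two or more crossings in a day recommend preventative action.
"""

from datetime import date

import somrisk as sr

stations, events = sr.simulate_study(seed=1)
profiles = sr.baseline_profiles(stations, events, seed=3)
tables = {s: sr.threshold_table(p) for s, p in profiles.items()}
print("summer threshold table (first/last day):")
print(tables["summer"].table.round(2).iloc[[0, -1]].to_string())

# a fresh summer window carrying the injected anomaly
series = sr.simulate_station(sr.SUMMER, n_days=10,
                             start_date=date(2018, 6, 1), seed=4)
series, _ = sr.inject_kill_signature(series, date(2018, 6, 10),
                                     sr.SUMMER_KILL)
window = sr.extract_window(series, date(2018, 6, 10))
print("\ndaily warning levels for an injected summer kill window:")
for state in sr.evaluate_warnings(window, tables["summer"]):
    crossed = ",".join(sorted(state.crossed)) or "-"
    print(f"  day {state.day}: {state.level:8s} crossed: {crossed}")

quiet = sr.evaluate_warnings(profiles["summer"].mean.copy(), tables["summer"])
print("baseline-mean window levels:", {s.level for s in quiet})
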