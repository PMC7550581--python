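"""Seeded synthetic hourly weather with injectable fish-kill signatures.

The generator emulates the structure of hourly records from a subtropical
river-basin weather station: two seasonal regimes (summer with low air
pressure and high temperature, non-summer with the opposite contrast), a
24-hour temperature cycle, AR(1)-persistent noise, a memoryless storm
process, and wind-direction regimes (diurnal rotation in summer, a steady
northeasterly otherwise).  Kill signatures perturb a single 7-day window
ending on the reported date, mirroring the anomaly patterns seen before
real kill events: depressed air pressure, elevated temperature, damped
wind speed and concentrated late-window storms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd

CHANNELS = ("AP", "T", "WS", "WD", "R")

#: hours per bundling window (7 days)
WINDOW_HOURS = 168


@dataclass(frozen=True)
class SeasonParams:
    """Regime parameters for one season.

    Means/SDs are marginal values of the simulated channel: ``ap_sd`` etc.
    are the stationary standard deviations of the AR(1) noise added to the
    seasonal mean, not innovation SDs.
    """

    season_label: str                    # "summer" | "non_summer"
    ap_mean: float                       # hPa
    ap_sd: float
    t_mean: float                        # degC
    t_sd: float
    t_diurnal_amp: float                 # degC, amplitude of the 24-h cycle
    ws_mean: float                       # m/s
    ws_sd: float
    wd_regime: str                       # "constant_NE" | "diurnal_rotation"
    storm_rate: float                    # expected storm onsets per day
    storm_intensity_mean: float          # mm/h, exponential mean
    ar1_coef: float = 0.8                # hourly persistence, in [0, 1)

    def __post_init__(self) -> None:
        if self.season_label not in ("summer", "non_summer"):
            raise ValueError(f"unknown season label {self.season_label!r}")
        if self.wd_regime not in ("constant_NE", "diurnal_rotation"):
            raise ValueError(f"unknown wind regime {self.wd_regime!r}")
        for name in ("ap_sd", "t_sd", "ws_sd", "storm_intensity_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ValueError("ar1_coef must be in [0, 1)")
        if self.storm_rate < 0:
            raise ValueError("storm_rate must be >= 0")


#: Default summer regime: low pressure, high temperature, rotating winds.
SUMMER = SeasonParams(
    season_label="summer", ap_mean=1003.0, ap_sd=2.0,
    t_mean=29.0, t_sd=1.5, t_diurnal_amp=3.0,
    ws_mean=2.0, ws_sd=0.8, wd_regime="diurnal_rotation",
    storm_rate=0.5, storm_intensity_mean=1.0,
)

#: Default non-summer regime: high pressure, cooler, steady northeasterly.
NON_SUMMER = SeasonParams(
    season_label="non_summer", ap_mean=1010.0, ap_sd=2.0,
    t_mean=23.0, t_sd=1.5, t_diurnal_amp=2.0,
    ws_mean=2.0, ws_sd=0.8, wd_regime="constant_NE",
    storm_rate=0.7, storm_intensity_mean=0.8,
)


@dataclass(frozen=True)
class KillSignature:
    """Per-day perturbation applied to the 7-day window before a kill.

    ``*_by_day`` arrays index day 1 (earliest) .. day 7 (reported date).
    """

    kill_type: str                       # "summer" | "non_summer"
    ap_offset_by_day: tuple[float, ...]  # hPa, added
    t_offset_by_day: tuple[float, ...]   # degC, added
    ws_scale_by_day: tuple[float, ...]   # multiplies WS, each in [0, 1.5]
    storm_boost_days: frozenset[int]     # day indices 1..7
    storm_boost_intensity: float         # mm/h added on boosted days

    def __post_init__(self) -> None:
        if self.kill_type not in ("summer", "non_summer"):
            raise ValueError(f"unknown kill type {self.kill_type!r}")
        for name in ("ap_offset_by_day", "t_offset_by_day", "ws_scale_by_day"):
            if len(getattr(self, name)) != 7:
                raise ValueError(f"{name} must have length 7")
        if any(not 0.0 <= s <= 1.5 for s in self.ws_scale_by_day):
            raise ValueError("ws_scale_by_day entries must lie in [0, 1.5]")
        if any(d not in range(1, 8) for d in self.storm_boost_days):
            raise ValueError("storm_boost_days must be day indices 1..7")


#: Summer kill anomaly: pressure sagging through the week, temperature near
#: +1 SD, damped mid-week winds and concentrated storms on days 5-7.
SUMMER_KILL = KillSignature(
    kill_type="summer",
    ap_offset_by_day=(-1.0, -1.0, -2.0, -2.0, -3.0, -3.0, -3.0),
    t_offset_by_day=(1.0, 1.0, 1.5, 2.0, 2.0, 2.0, 2.0),
    ws_scale_by_day=(0.9, 0.6, 0.5, 0.6, 0.5, 0.6, 0.9),
    storm_boost_days=frozenset({5, 6, 7}),
    storm_boost_intensity=1.8,
)

#: Non-summer kill anomaly: early pressure drop, mildly raised temperature
#: on days 1-3, very low wind on days 3-6 and storms on days 3-4 and 6.
NON_SUMMER_KILL = KillSignature(
    kill_type="non_summer",
    ap_offset_by_day=(-1.0, -2.0, -3.0, -3.0, -2.5, -2.5, -2.5),
    t_offset_by_day=(1.5, 1.5, 1.5, 0.5, 0.5, 0.5, 0.5),
    ws_scale_by_day=(0.9, 0.8, 0.3, 0.3, 0.3, 0.3, 0.8),
    storm_boost_days=frozenset({3, 4, 6}),
    storm_boost_intensity=1.8,
)

DEFAULT_SIGNATURES = {"summer": SUMMER_KILL, "non_summer": NON_SUMMER_KILL}


@dataclass
class StationSeries:
    """One station's hourly meteorology (AP, T, WS, WD, R).

    ``frame`` is indexed by an hourly, strictly increasing DatetimeIndex;
    missing values are NaN.
    """

    station_id: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"missing channels: {missing}")
        idx = self.frame.index
        if len(idx) > 1:
            deltas = np.diff(idx.asi8)
            if not np.all(deltas == 3_600_000_000_000):
                raise ValueError("timestamps must be uniform hourly and increasing")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.frame["WS"].to_numpy()) < 0:
                raise ValueError("WS must be >= 0")
            if np.nanmin(self.frame["R"].to_numpy()) < 0:
                raise ValueError("R must be >= 0")

    def copy(self) -> "StationSeries":
        return StationSeries(self.station_id, self.frame.copy())

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class KillEvent:
    """A reported fish-kill event tied to its nearest station."""

    event_id: str
    station_id: str
    reported_date: date
    kill_type: str | None = None
    estimated_weight: float | None = None  # kg
    excluded: bool = False                 # industrial-pollution exclusion


def _ar1(rng: np.random.Generator, n: int, marginal_sd: float, coef: float) -> np.ndarray:
    """Stationary AR(1) path with the given marginal SD."""
    if marginal_sd == 0.0:
        return np.zeros(n)
    innov_sd = marginal_sd * np.sqrt(1.0 - coef**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, marginal_sd)
    for t in range(1, n):
        x[t] = coef * x[t - 1] + eps[t]
    return x


def simulate_station(
    params: SeasonParams,
    n_days: int,
    start_date: date,
    seed: int,
    station_id: str | None = None,
    diurnal_peak_hour: int = 14,
    storm_duration: int = 3,
) -> StationSeries:
    """Simulate a gap-free hourly station series for one seasonal regime.

    Temperature carries a cosine diurnal cycle peaking at
    ``diurnal_peak_hour`` (local time); AP/T/WS ride AR(1) noise around the
    regime means; rain is a marked storm process with Bernoulli hourly
    onsets at ``storm_rate / 24``, fixed ``storm_duration`` and exponential
    hourly intensities.  Identical seeds give identical output.
    """
    if n_days < 8:
        raise ValueError("n_days must be >= 8 (one window plus lead-in)")
    rng = np.random.default_rng(seed)
    n = n_days * 24
    index = pd.date_range(pd.Timestamp(start_date), periods=n, freq="h")
    hour = index.hour.to_numpy()

    ap = params.ap_mean + _ar1(rng, n, params.ap_sd, params.ar1_coef)
    diurnal = params.t_diurnal_amp * np.cos(2 * np.pi * (hour - diurnal_peak_hour) / 24.0)
    t = params.t_mean + diurnal + _ar1(rng, n, params.t_sd, params.ar1_coef)
    ws = np.maximum(0.0, params.ws_mean + _ar1(rng, n, params.ws_sd, params.ar1_coef))

    if params.wd_regime == "constant_NE":
        wd = (45.0 + rng.normal(0.0, 10.0, size=n)) % 360.0
    else:  # diurnal_rotation: one full turn per day
        wd = (90.0 + 15.0 * hour + rng.normal(0.0, 5.0, size=n)) % 360.0

    r = np.zeros(n)
    if params.storm_rate > 0:
        onsets = rng.random(n) < params.storm_rate / 24.0
        for i in np.flatnonzero(onsets):
            stop = min(n, i + storm_duration)
            r[i:stop] += rng.exponential(params.storm_intensity_mean, size=stop - i)

    frame = pd.DataFrame(
        {"AP": ap, "T": t, "WS": ws, "WD": wd, "R": r}, index=index
    )
    sid = station_id or f"SYN-{params.season_label.upper()}"
    return StationSeries(sid, frame)


def kill_window_index(
    series: StationSeries, reported_date: date, window_days: int = 7
) -> pd.DatetimeIndex:
    """The hourly timestamps of the window ending on the reported date.

    The default 7-day window covers 168 hours: day 1 is six days before the
    reported date and day 7 is the reported date itself.
    """
    start = pd.Timestamp(reported_date) - pd.Timedelta(days=window_days - 1)
    window = pd.date_range(start, periods=window_days * 24, freq="h")
    if not window.isin(series.frame.index).all():
        raise ValueError(
            f"window {window[0]}..{window[-1]} not fully covered by "
            f"station {series.station_id}"
        )
    return window


def inject_kill_signature(
    series: StationSeries,
    reported_date: date,
    signature: KillSignature,
    event_id: str = "E1",
) -> tuple[StationSeries, KillEvent]:
    """Superimpose a kill anomaly on the 7-day window ending on ``reported_date``.

    Within the window only: AP and T are shifted by per-day offsets, WS is
    multiplied by per-day scales, and ``storm_boost_intensity`` of rainfall
    is added on the boosted days.  Data outside the window are untouched.
    """
    window = kill_window_index(series, reported_date)
    out = series.copy()
    frame = out.frame
    for day in range(1, 8):
        hours = window[(day - 1) * 24: day * 24]
        frame.loc[hours, "AP"] += signature.ap_offset_by_day[day - 1]
        frame.loc[hours, "T"] += signature.t_offset_by_day[day - 1]
        frame.loc[hours, "WS"] *= signature.ws_scale_by_day[day - 1]
        if day in signature.storm_boost_days:
            frame.loc[hours, "R"] += signature.storm_boost_intensity
    event = KillEvent(
        event_id=event_id,
        station_id=series.station_id,
        reported_date=reported_date,
        kill_type=signature.kill_type,
    )
    return out, event


def make_gaps(
    series: StationSeries,
    gap_fraction: float,
    max_gap_len: int,
    seed: int,
) -> StationSeries:
    """Knock out ~``gap_fraction`` of hours in contiguous runs.

    Runs have length <= ``max_gap_len`` and never touch the first or last
    hour of the series; all channels are blanked at the chosen hours.
    """
    if not 0.0 <= gap_fraction < 0.2:
        raise ValueError("gap_fraction must lie in [0, 0.2)")
    out = series.copy()
    n = len(out)
    target = int(round(gap_fraction * n))
    if target == 0:
        return out
    rng = np.random.default_rng(seed)
    missing = np.zeros(n, dtype=bool)
    # place runs until the target count is reached; interior hours only,
    # and never touching an existing run (keeps run length <= max_gap_len)
    attempts = 0
    while missing.sum() < target and attempts < 100 * target:
        attempts += 1
        length = int(rng.integers(1, max_gap_len + 1))
        start = int(rng.integers(1, n - 1))
        stop = min(start + length, n - 1)
        if missing[max(0, start - 1):min(n, stop + 1)].any():
            continue
        missing[start:stop] = True
    out.frame.iloc[np.flatnonzero(missing)] = np.nan
    return out


def default_events(
    year: int = 2017,
    n_summer: int = 11,
    n_non_summer: int = 8,
) -> tuple[list[tuple[date, str]], list[tuple[date, str]]]:
    """Reported dates for the default synthetic study: 11 summer events
    (mid-June to mid-September) and 8 non-summer events (April-May).

    Returns (summer, non_summer) lists of (reported_date, kill_type).
    """
    summer_start = date(year, 6, 15)
    summer = [
        (summer_start + pd.Timedelta(days=9 * k).to_pytimedelta(), "summer")
        for k in range(n_summer)
    ]
    ns_start = date(year, 4, 10)
    non_summer = [
        (ns_start + pd.Timedelta(days=7 * k).to_pytimedelta(), "non_summer")
        for k in range(n_non_summer)
    ]
    return summer, non_summer


def simulate_study(
    seed: int,
    n_summer: int = 11,
    n_non_summer: int = 8,
    summer_params: SeasonParams = SUMMER,
    non_summer_params: SeasonParams = NON_SUMMER,
    signatures: dict[str, KillSignature] | None = None,
    year: int = 2017,
    include_reference: bool = True,
) -> tuple[dict[str, StationSeries], list[KillEvent]]:
    """Simulate the default study with injected kill events.

    One kill station per seasonal regime carries the injected signatures at
    spread-out reported dates (default 11 summer + 8 non-summer = 19
    events).  One clean reference station per regime (no injections) stands
    in for the multi-year, multi-station depth of real records, supplying
    kill-free windows for the baseline profiles.
    """
    signatures = signatures or DEFAULT_SIGNATURES
    rng = np.random.default_rng(seed)
    s_seed, ns_seed, s_ref_seed, ns_ref_seed = (
        int(x) for x in rng.integers(0, 2**31 - 1, size=4))
    summer_series = simulate_station(
        summer_params, n_days=122, start_date=date(year, 6, 1),
        seed=s_seed, station_id="SYN-SUMMER",
    )
    ns_series = simulate_station(
        non_summer_params, n_days=61, start_date=date(year, 4, 1),
        seed=ns_seed, station_id="SYN-NONSUM",
    )
    summer_dates, ns_dates = default_events(year, n_summer, n_non_summer)

    events: list[KillEvent] = []
    k = 0
    for dates, station in ((summer_dates, "summer"), (ns_dates, "non_summer")):
        series = summer_series if station == "summer" else ns_series
        for reported, kill_type in dates:
            k += 1
            series, ev = inject_kill_signature(
                series, reported, signatures[kill_type], event_id=f"E{k}"
            )
            events.append(ev)
        if station == "summer":
            summer_series = series
        else:
            ns_series = series
    stations = {s.station_id: s for s in (summer_series, ns_series)}
    if include_reference:
        stations["SYN-SUMMER-REF"] = simulate_station(
            summer_params, n_days=122, start_date=date(year, 6, 1),
            seed=s_ref_seed, station_id="SYN-SUMMER-REF",
        )
        stations["SYN-NONSUM-REF"] = simulate_station(
            non_summer_params, n_days=61, start_date=date(year, 4, 1),
            seed=ns_ref_seed, station_id="SYN-NONSUM-REF",
        )
    return stations, events
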