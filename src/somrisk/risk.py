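"""Non-kill baselines, hourly significance tests and warning thresholds.

The risk analysis compares the 7-day meteorological windows preceding kill
events with seasonal "normal" baselines built from windows that overlap no
kill event.  Per window-hour Welch tests locate the variables and hours
that differ; per-day warning bounds are the extremes of the baseline
mean +/- 1 SD envelope.  One crossing is a warning; two or more concurrent
crossings recommend preventative action (e.g., water oxygenation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import KillEvent, StationSeries, kill_window_index

logger = logging.getLogger(__name__)

#: variables compared against baselines
RISK_VARIABLES = ("AP", "T", "WS", "R")


def season_of(month: int, summer_months=frozenset({6, 7, 8, 9})) -> str:
    return "summer" if month in summer_months else "non_summer"


def extract_window(
    series: StationSeries, end_date, window_days: int = 7
) -> pd.DataFrame:
    """The 168 x 4 (AP, T, WS, R) frame of the window ending on ``end_date``,
    indexed by window-hour 1..168."""
    window = kill_window_index(series, end_date, window_days)
    sub = series.frame.loc[window, list(RISK_VARIABLES)].reset_index(drop=True)
    sub.index = pd.RangeIndex(1, len(sub) + 1, name="window_hour")
    return sub


@dataclass
class BaselineProfile:
    """Per window-hour mean/SD of AP, T, WS, R over non-kill windows."""

    season: str
    mean: pd.DataFrame       # 168 rows x 4 variables
    sd: pd.DataFrame
    n_windows: int


def sample_baseline_windows(
    series: StationSeries,
    events: list[KillEvent],
    seed: int,
    n_windows: int | None = None,
    window_days: int = 7,
    allow_overlap: bool = False,
) -> list[pd.Timestamp]:
    """End dates of windows that overlap no kill window at this station.

    Candidates are daily; selection is a seeded shuffle, greedy so chosen
    windows do not overlap each other unless ``allow_overlap``.
    """
    idx = series.frame.index
    span = pd.Timedelta(days=window_days - 1)
    kill_ends = [pd.Timestamp(e.reported_date) for e in events
                 if e.station_id == series.station_id and not e.excluded]
    first_end = idx[0].normalize() + span
    candidates = pd.date_range(first_end, idx[-1].normalize(), freq="D")
    ok = []
    for end in candidates:
        start = end - span
        if start < idx[0] or end + pd.Timedelta(hours=23) > idx[-1]:
            continue
        if any(start <= ke and ke - span <= end for ke in kill_ends):
            continue
        ok.append(end)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ok))
    chosen: list[pd.Timestamp] = []
    for i in order:
        end = ok[i]
        if not allow_overlap and any(abs(end - c) <= span for c in chosen):
            continue
        chosen.append(end)
        if n_windows is not None and len(chosen) == n_windows:
            break
    if allow_overlap:
        logger.warning("baseline windows may overlap; tests assume independence")
    return sorted(chosen)


def stack_windows(
    series: StationSeries, end_dates, window_days: int = 7
) -> dict[str, np.ndarray]:
    """Stack windows into per-variable (n_windows, 168) arrays."""
    per_var: dict[str, list[np.ndarray]] = {v: [] for v in RISK_VARIABLES}
    for end in end_dates:
        win = extract_window(series, end, window_days)
        for v in RISK_VARIABLES:
            per_var[v].append(win[v].to_numpy())
    return {v: np.asarray(a) for v, a in per_var.items()}


def baseline_profiles(
    series_by_station: dict[str, StationSeries],
    events: list[KillEvent],
    season_def=season_of,
    seed: int = 0,
    n_windows: int | None = None,
    allow_overlap: bool = False,
) -> dict[str, BaselineProfile]:
    """Seasonal per-hour baselines from windows overlapping no kill window.

    A window's season is the season of its end date.  Errors if a season
    has fewer than two usable windows.
    """
    pools: dict[str, list[tuple[StationSeries, pd.Timestamp]]] = {}
    for k, (sid, series) in enumerate(sorted(series_by_station.items())):
        ends = sample_baseline_windows(
            series, events, seed=seed + k, n_windows=n_windows,
            allow_overlap=allow_overlap,
        )
        for end in ends:
            pools.setdefault(season_def(end.month), []).append((series, end))

    if not pools:
        raise ValueError("fewer than 2 usable non-kill windows in any season")
    profiles = {}
    for season, pool in pools.items():
        if n_windows is not None:
            pool = pool[:n_windows]
        if len(pool) < 2:
            raise ValueError(f"fewer than 2 usable non-kill windows in "
                             f"season {season!r}")
        stacks = {v: [] for v in RISK_VARIABLES}
        for series, end in pool:
            win = extract_window(series, end)
            for v in RISK_VARIABLES:
                stacks[v].append(win[v].to_numpy())
        mean = pd.DataFrame(
            {v: np.mean(stacks[v], axis=0) for v in RISK_VARIABLES},
            index=pd.RangeIndex(1, 169, name="window_hour"),
        )
        sd = pd.DataFrame(
            {v: np.std(stacks[v], axis=0, ddof=1) for v in RISK_VARIABLES},
            index=mean.index,
        )
        profiles[season] = BaselineProfile(season, mean, sd, len(pool))
    return profiles


@dataclass
class SignificanceSeries:
    """Per window-hour Welch-test p-values, kill vs baseline windows."""

    kill_type: str
    p: pd.DataFrame                 # 168 rows x 4 variables, values in [0, 1]
    frac_significant: pd.Series     # per variable, fraction of hours p < alpha
    alpha: float


def hourly_tests(
    kill_windows: dict[str, np.ndarray],
    baseline_windows: dict[str, np.ndarray],
    alpha: float = 0.05,
    kill_type: str = "kill",
) -> SignificanceSeries:
    """Unequal-variance two-sample tests per window-hour and variable.

    Degenerate slots follow the convention: both sides constant with equal
    means -> p = 1; constant with unequal means -> p = 0 (logged).
    """
    p_cols = {}
    for v in RISK_VARIABLES:
        a, b = kill_windows[v], baseline_windows[v]
        if a.shape[0] < 2 or b.shape[0] < 2:
            raise ValueError("need >= 2 kill and >= 2 baseline windows")
        import warnings as _warnings
        with np.errstate(divide="ignore", invalid="ignore"), \
                _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            p = stats.ttest_ind(a, b, axis=0, equal_var=False).pvalue
        degen = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
        if degen.any():
            equal = np.isclose(a.mean(axis=0), b.mean(axis=0))
            p = np.where(degen, np.where(equal, 1.0, 0.0), p)
            logger.info("%s: %d degenerate zero-variance slots", v, degen.sum())
        p_cols[v] = p
    p_frame = pd.DataFrame(p_cols, index=pd.RangeIndex(1, 169, name="window_hour"))
    frac = (p_frame < alpha).mean()
    return SignificanceSeries(kill_type, p_frame, frac, alpha)


@dataclass
class ThresholdTable:
    """Daily warning bounds from the baseline mean +/- 1 SD envelope.

    ``table`` is indexed by day 1..7 with columns AP_min_normal,
    AP_min_minus1sd, T_max_normal, T_max_plus1sd, WS_min_normal,
    WS_min_minus1sd, R_max_normal, R_max_plus1sd.
    """

    season: str
    table: pd.DataFrame


def threshold_table(baseline: BaselineProfile) -> ThresholdTable:
    """Early-warning bounds per day: extremes of the mean and mean±SD.

    Low-side variables (AP, WS) warn below the minimum of (mean − SD) over
    the day's 24 slots; high-side variables (T, R) warn above the maximum
    of (mean + SD).
    """
    if len(baseline.mean) != 168:
        raise ValueError("baseline must cover 168 window-hours")
    day = (baseline.mean.index.to_numpy() - 1) // 24 + 1
    rows = []
    for d in range(1, 8):
        m = baseline.mean[day == d]
        s = baseline.sd[day == d]
        rows.append({
            "day": d,
            "AP_min_normal": m["AP"].min(),
            "AP_min_minus1sd": (m["AP"] - s["AP"]).min(),
            "T_max_normal": m["T"].max(),
            "T_max_plus1sd": (m["T"] + s["T"]).max(),
            "WS_min_normal": m["WS"].min(),
            "WS_min_minus1sd": (m["WS"] - s["WS"]).min(),
            "R_max_normal": m["R"].max(),
            "R_max_plus1sd": (m["R"] + s["R"]).max(),
        })
    return ThresholdTable(baseline.season, pd.DataFrame(rows).set_index("day"))


@dataclass(frozen=True)
class WarningState:
    day: int
    crossed: frozenset[str]
    level: str                 # "none" | "warning" | "action"


def evaluate_warnings(
    window: pd.DataFrame,
    table: ThresholdTable,
    season: str | None = None,
) -> list[WarningState]:
    """Daily warning levels for one 7-day window against a threshold table.

    A variable crosses when the day's min AP or min WS drops below its
    −1 SD bound, or the day's max T or max hourly R rises above its +1 SD
    bound.  One crossing → warning; two or more → action.
    """
    if season is not None and season != table.season:
        raise ValueError(f"window season {season!r} does not match table "
                         f"season {table.season!r}")
    if len(window) != 168:
        raise ValueError("window must cover 168 hours")
    values = window.reset_index(drop=True)
    states = []
    for d in range(1, 8):
        sub = values.iloc[(d - 1) * 24: d * 24]
        bounds = table.table.loc[d]
        crossed = set()
        if sub["AP"].min() < bounds["AP_min_minus1sd"]:
            crossed.add("AP")
        if sub["T"].max() > bounds["T_max_plus1sd"]:
            crossed.add("T")
        if sub["WS"].min() < bounds["WS_min_minus1sd"]:
            crossed.add("WS")
        if sub["R"].max() > bounds["R_max_plus1sd"]:
            crossed.add("R")
        level = "none" if not crossed else ("warning" if len(crossed) == 1
                                            else "action")
        states.append(WarningState(day=d, crossed=frozenset(crossed),
                                   level=level))
    return states
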