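"""Gap filling, wind decomposition, 7-day event bundling and normalization.

Each kill event is bundled with the 168 hourly records of the 7-day window
ending on its reported date.  The bundled analysis variables are air
pressure (AP), temperature (T), the signed wind components WY (north-south)
and WX (east-west), precipitation (R) and the fish-kill-time variable F
(day index 1..7, day 7 = reported date).  All six are min-max normalized to
[0, 1] over the full matrix before clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import CHANNELS, WINDOW_HOURS, KillEvent, StationSeries, kill_window_index

logger = logging.getLogger(__name__)

#: analysis-variable order of the normalized matrix
VARIABLES = ("AP", "T", "WY", "WX", "R", "F")


def decompose_wind(ws, wd):
    """Split wind into signed N-S and E-W speed components.

    WY = WS*cos(WD), WX = WS*sin(WD), with WD the bearing in degrees; the
    decomposition preserves speed: sqrt(WY^2 + WX^2) = WS.
    """
    ws = np.asarray(ws, dtype=float)
    wd = np.asarray(wd, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(ws) < 0:
            raise ValueError("wind speed must be >= 0")
    rad = np.deg2rad(wd)
    return ws * np.cos(rad), ws * np.sin(rad)


def recompose_wind(wy, wx):
    """Inverse of :func:`decompose_wind`: (WS, WD in [0, 360))."""
    wy = np.asarray(wy, dtype=float)
    wx = np.asarray(wx, dtype=float)
    ws = np.hypot(wy, wx)
    wd = np.rad2deg(np.arctan2(wx, wy)) % 360.0
    return ws, wd


def interpolate_missing(series: StationSeries) -> StationSeries:
    """Fill internal gaps by linear interpolation, per channel.

    Wind direction is interpolated on its unit-circle components and
    reconstituted, so a gap spanning 350°→10° passes through north rather
    than south.  The first and last hour of every channel must be present.
    """
    frame = series.frame
    for channel in CHANNELS:
        col = frame[channel]
        for pos, label in ((0, frame.index[0]), (-1, frame.index[-1])):
            if pd.isna(col.iloc[pos]):
                raise ValueError(
                    f"channel {channel} missing at endpoint {label}; "
                    "cannot interpolate"
                )
    out = series.copy()
    for channel in ("AP", "T", "WS", "R"):
        out.frame[channel] = out.frame[channel].interpolate(method="linear")
    # circular interpolation for direction
    wd = out.frame["WD"]
    u = np.cos(np.deg2rad(wd))
    v = np.sin(np.deg2rad(wd))
    u = pd.Series(u, index=wd.index).interpolate(method="linear")
    v = pd.Series(v, index=wd.index).interpolate(method="linear")
    out.frame["WD"] = np.rad2deg(np.arctan2(v, u)) % 360.0
    return out


@dataclass
class BundledMatrix:
    """Raw bundled records plus (after :func:`normalize`) the [0,1] matrix.

    ``records`` columns: event_id, F_day, hour, AP, T, WY, WX, R, F.
    ``normalized`` has one column per entry of :data:`VARIABLES`.
    """

    records: pd.DataFrame
    normalized: pd.DataFrame | None = None
    col_min: pd.Series | None = None
    col_max: pd.Series | None = None

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def event_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["event_id"]))

    def values(self) -> np.ndarray:
        """The n x 6 normalized array fed to the SOM."""
        if self.normalized is None:
            raise ValueError("matrix not normalized yet")
        return self.normalized.to_numpy()

    def denormalize(self, norm: pd.DataFrame | np.ndarray) -> pd.DataFrame:
        """Map normalized values back to raw units using the stored min/max."""
        if self.col_min is None or self.col_max is None:
            raise ValueError("matrix not normalized yet")
        arr = np.asarray(norm, dtype=float)
        span = (self.col_max - self.col_min).to_numpy()
        raw = arr * span + self.col_min.to_numpy()
        # zero-range columns were pinned at 0.5; restore the constant
        const = span == 0
        if const.any():
            raw[:, const] = self.col_min.to_numpy()[const]
        return pd.DataFrame(raw, columns=list(VARIABLES))


def bundle_events(
    series_by_station: dict[str, StationSeries],
    events: list[KillEvent],
    window_days: int = 7,
    f_hourly: bool = False,
) -> BundledMatrix:
    """Bundle each included event with its 7-day hourly window.

    Emits ``window_days * 24`` records per included event with F_day = 1 for
    the earliest day through 7 on the reported date; excluded events are
    skipped with a logged reason.  F is the day index by default, or hourly
    resolution (day + hour/24) when ``f_hourly``.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    n_hours = window_days * 24
    rows = []
    for event in events:
        if event.excluded:
            logger.info("event %s excluded (industrial pollution); skipped",
                        event.event_id)
            continue
        if event.station_id not in series_by_station:
            raise ValueError(f"event {event.event_id}: unknown station "
                             f"{event.station_id}")
        series = series_by_station[event.station_id]
        window = kill_window_index(series, event.reported_date,
                                   window_days=window_days)
        sub = series.frame.loc[window]
        bad = sub.index[sub[list(CHANNELS)].isna().any(axis=1)]
        if len(bad):
            raise ValueError(
                f"event {event.event_id}: missing hours in window: "
                f"{list(bad[:5])}{'...' if len(bad) > 5 else ''}"
            )
        wy, wx = decompose_wind(sub["WS"].to_numpy(), sub["WD"].to_numpy())
        hours = np.arange(n_hours)
        f_day = hours // 24 + 1
        f = f_day + hours % 24 / 24.0 if f_hourly else f_day.astype(float)
        rows.append(pd.DataFrame({
            "event_id": event.event_id,
            "F_day": f_day,
            "hour": hours % 24,
            "AP": sub["AP"].to_numpy(),
            "T": sub["T"].to_numpy(),
            "WY": wy,
            "WX": wx,
            "R": sub["R"].to_numpy(),
            "F": f,
        }))
    if not rows:
        raise ValueError("no included events to bundle")
    records = pd.concat(rows, ignore_index=True)
    logger.info("bundled %d events -> %d records", len(rows), len(records))
    return BundledMatrix(records=records)


def normalize(matrix: BundledMatrix) -> BundledMatrix:
    """Min-max scale each analysis variable to [0, 1] over the full matrix.

    Per-column min/max are stored so raw values round-trip exactly;
    zero-range columns map to the uninformative constant 0.5.
    """
    if matrix.n < 2:
        raise ValueError("need at least 2 records to normalize")
    raw = matrix.records[list(VARIABLES)].astype(float)
    col_min = raw.min(axis=0)
    col_max = raw.max(axis=0)
    span = col_max - col_min
    norm = pd.DataFrame(0.5, index=raw.index, columns=raw.columns)
    ok = span > 0
    norm.loc[:, ok] = (raw.loc[:, ok] - col_min[ok]) / span[ok]
    return BundledMatrix(
        records=matrix.records,
        normalized=norm,
        col_min=col_min,
        col_max=col_max,
    )
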