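"""Plain-text readers/writers for every pipeline artifact.

Station series and event tables are simple CSVs (empty cells = missing);
trained-map component planes, neuron summaries and threshold tables are
CSVs; scan results and warning states are JSON.  Readers validate cell
types and report the offending line number.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import VARIABLES, BundledMatrix
from .risk import ThresholdTable
from .som import MapSizeScan, SOMGrid
from .synthetic import CHANNELS, KillEvent, StationSeries

STATION_HEADER = ["timestamp", *CHANNELS]
EVENT_HEADER = ["event_id", "station_id", "reported_date", "kill_type"]


def write_station_csv(series: StationSeries, path) -> None:
    """`timestamp,AP,T,WS,WD,R` with ISO timestamps; missing -> empty cell."""
    frame = series.frame.copy()
    frame.insert(0, "timestamp", frame.index.strftime("%Y-%m-%dT%H:%M:%S"))
    frame.to_csv(path, index=False)


def _numeric_or_report(raw: pd.Series, column: str, path) -> pd.Series:
    converted = pd.to_numeric(raw, errors="coerce")
    bad = converted.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: header line plus 1-based numbering
        raise ValueError(
            f"{path}: non-numeric value {raw.iloc[row]!r} in column "
            f"{column!r} at line {row + 2}"
        )
    return converted


def read_station_csv(path, station_id: str | None = None) -> StationSeries:
    """Read a station CSV; empty cells parse as missing (NaN), never zero."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    missing_cols = [c for c in STATION_HEADER if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    index = pd.DatetimeIndex(pd.to_datetime(frame["timestamp"]))
    data = {c: _numeric_or_report(frame[c], c, path) for c in CHANNELS}
    out = pd.DataFrame(data)
    out.index = index
    stem = path.stem
    if stem.startswith("station_"):
        stem = stem[len("station_"):]
    return StationSeries(station_id or stem, out)


def write_events_csv(events: list[KillEvent], path) -> None:
    rows = [{
        "event_id": e.event_id,
        "station_id": e.station_id,
        "reported_date": e.reported_date.isoformat(),
        "kill_type": e.kill_type or "",
        "estimated_weight": "" if e.estimated_weight is None else e.estimated_weight,
        "excluded": int(e.excluded),
    } for e in events]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_events_csv(path) -> list[KillEvent]:
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    missing_cols = [c for c in EVENT_HEADER if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    events = []
    for i, row in frame.iterrows():
        try:
            reported = date.fromisoformat(row["reported_date"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad reported_date at line {i + 2}: "
                             f"{row['reported_date']!r}") from exc
        weight = row.get("estimated_weight")
        weight = None if weight in (None, "") or pd.isna(weight) else float(weight)
        excluded = row.get("excluded")
        excluded = (not pd.isna(excluded)) and str(excluded).strip() in ("1", "True", "true")
        kill_type = row.get("kill_type")
        kill_type = None if kill_type in (None, "") or pd.isna(kill_type) else kill_type
        events.append(KillEvent(
            event_id=str(row["event_id"]),
            station_id=str(row["station_id"]),
            reported_date=reported,
            kill_type=kill_type,
            estimated_weight=weight,
            excluded=excluded,
        ))
    return events


BUNDLED_COLUMNS = ["event_id", "F_day", "hour", "AP", "T", "WY", "WX", "R",
                   "F_norm", "AP_norm", "T_norm", "WY_norm", "WX_norm", "R_norm"]


def write_bundled_csv(matrix: BundledMatrix, path) -> None:
    out = matrix.records[["event_id", "F_day", "hour", "AP", "T", "WY",
                          "WX", "R"]].copy()
    if matrix.normalized is not None:
        for v in VARIABLES:
            out[f"{v}_norm"] = matrix.normalized[v].to_numpy()
        out = out[BUNDLED_COLUMNS]
    out.to_csv(path, index=False)


def write_component_planes(grid: SOMGrid, matrix: BundledMatrix, path) -> None:
    """Per-neuron denormalized weights: `neuron_row,neuron_col,AP,...,F`."""
    planes = matrix.denormalize(grid.weights)
    planes.insert(0, "neuron_col", np.arange(grid.n_neurons) % grid.cols)
    planes.insert(0, "neuron_row", np.arange(grid.n_neurons) // grid.cols)
    planes.to_csv(path, index=False)


def write_scan_json(scan: MapSizeScan, path) -> None:
    Path(path).write_text(json.dumps(scan.to_dict(), indent=2))


def write_threshold_csv(tables: dict[str, ThresholdTable], path) -> None:
    frames = []
    for season in sorted(tables):
        frame = tables[season].table.reset_index()
        frame.insert(0, "season", season)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_threshold_csv(path) -> dict[str, ThresholdTable]:
    frame = pd.read_csv(path)
    tables = {}
    for season, sub in frame.groupby("season"):
        tables[str(season)] = ThresholdTable(
            str(season), sub.drop(columns="season").set_index("day")
        )
    return tables


def write_warnings_jsonl(states_by_key: dict[str, list], path) -> None:
    """One JSON object per evaluated window: key, day, crossed, level."""
    with open(path, "w") as fh:
        for key, states in states_by_key.items():
            for s in states:
                fh.write(json.dumps({
                    "window": key, "day": s.day,
                    "crossed": sorted(s.crossed), "level": s.level,
                }) + "\n")
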