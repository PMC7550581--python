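"""Trace high-F neurons back to events and summarize neurons.

Neurons whose records sit close in time to the reported kill date carry a
high mean fish-kill-time value F; these "kill neurons" are identified by a
quantile rule, each event is attached to the kill neuron holding the
plurality of its late-window records, and neuron groups are labeled
summer / non-summer by the reported months of their events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import BundledMatrix
from .som import Assignment
from .synthetic import KillEvent

#: months counted as summer (June-September)
DEFAULT_SUMMER_MONTHS = frozenset({6, 7, 8, 9})


@dataclass(frozen=True)
class KillTypeLabel:
    event_id: str
    neuron: int | None            # assigned kill neuron, None if unclassified
    kill_type: str                # "summer" | "non_summer" | "unclassified"


def identify_kill_neurons(
    assignment: Assignment,
    matrix: BundledMatrix,
    quantile: float = 0.75,
) -> list[int]:
    """Neurons whose mean normalized F exceeds the given quantile.

    The quantile is taken over per-neuron mean F; the result is never empty
    (falls back to the max-F neuron set, so exact ties at the top are all
    returned).
    """
    if assignment.n == 0:
        raise ValueError("empty assignment")
    if assignment.n != matrix.n:
        raise ValueError("assignment and matrix cover different records")
    f = matrix.normalized["F"].to_numpy()
    mean_f = pd.Series(f).groupby(assignment.bmu).mean()
    cut = np.quantile(mean_f.to_numpy(), quantile)
    above = mean_f.index[mean_f > cut].tolist()
    if not above:
        above = mean_f.index[mean_f == mean_f.max()].tolist()
    return [int(i) for i in above]


def label_event_types(
    kill_neurons: list[int],
    assignment: Assignment,
    matrix: BundledMatrix,
    events: list[KillEvent],
    summer_months: frozenset[int] = DEFAULT_SUMMER_MONTHS,
    late_day_min: int = 6,
) -> list[KillTypeLabel]:
    """Attach events to kill neurons and label the groups by season.

    Each event goes to the kill neuron holding the plurality of its
    late-window (F_day >= ``late_day_min``) records; events with no late
    record in any kill neuron are unclassified.  A kill neuron's group is
    summer if the majority of its events were reported in
    ``summer_months``, else non-summer.
    """
    records = matrix.records
    kill_set = set(kill_neurons)
    by_event: dict[str, int | None] = {}
    included = [e for e in events if not e.excluded]
    for event in included:
        mask = ((records["event_id"] == event.event_id)
                & (records["F_day"] >= late_day_min)).to_numpy()
        if not mask.any():
            raise ValueError(f"event {event.event_id} has no late-window records")
        late_bmus = assignment.bmu[mask]
        counts = pd.Series(late_bmus).value_counts()
        counts = counts[counts.index.isin(kill_set)]
        by_event[event.event_id] = int(counts.idxmax()) if len(counts) else None

    # label each kill neuron's group by majority reported month
    group_type: dict[int, str] = {}
    for neuron in kill_set:
        members = [e for e in included if by_event[e.event_id] == neuron]
        if not members:
            continue
        n_summer = sum(e.reported_date.month in summer_months for e in members)
        group_type[neuron] = (
            "summer" if n_summer > len(members) / 2 else "non_summer"
        )

    labels = []
    for event in included:
        neuron = by_event[event.event_id]
        kind = "unclassified" if neuron is None else group_type[neuron]
        labels.append(KillTypeLabel(event.event_id, neuron, kind))
    return labels


def neuron_summaries(
    assignment: Assignment,
    matrix: BundledMatrix,
    rain_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-neuron summaries of the raw bundled variables.

    Columns: record count, mean AP/T/WY/WX, WS_mean (mean of
    sqrt(WY^2+WX^2)), average R (mm/h), total R (mm, sum of hourly rain),
    duration of R (number of distinct window hour-slots 1..168 whose
    member-record mean rain exceeds ``rain_threshold``), and mean
    normalized F.  Counts over all neurons partition the records.
    """
    if assignment.n != matrix.n:
        raise ValueError("assignment and matrix cover different records")
    rec = matrix.records.copy()
    rec["neuron"] = assignment.bmu
    rec["WS"] = np.hypot(rec["WY"], rec["WX"])
    rec["slot"] = (rec["F_day"] - 1) * 24 + rec["hour"] + 1
    rec["F_norm"] = matrix.normalized["F"].to_numpy()

    rows = []
    for neuron, g in rec.groupby("neuron", sort=True):
        slot_mean_r = g.groupby("slot")["R"].mean()
        rows.append({
            "neuron": int(neuron),
            "count": len(g),
            "AP": g["AP"].mean(),
            "T": g["T"].mean(),
            "WY": g["WY"].mean(),
            "WX": g["WX"].mean(),
            "WS": g["WS"].mean(),
            "avg_R": g["R"].mean(),
            "total_R": g["R"].sum(),
            "duration_R": int((slot_mean_r > rain_threshold).sum()),
            "mean_F": g["F_norm"].mean(),
        })
    return pd.DataFrame(rows).set_index("neuron")
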