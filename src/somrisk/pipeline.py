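"""End-to-end orchestration: simulate -> bundle -> train -> classify -> risk.

``run_pipeline`` executes the whole study on synthetic (or loaded) data and
writes every stage artifact, a manifest and the resolved configuration to a
run directory.  A single master seed fans out to per-stage seeds through
``numpy.random.SeedSequence(master_seed).spawn``, so any stage can be rerun
in isolation and the whole run is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify, io, preprocess, risk, som, synthetic

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "bundle", "train", "classify", "risk")


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run (defaults = demo study)."""

    # input: either paths to station/event CSVs, or simulation parameters
    station_paths: dict[str, str] | None = None
    events_path: str | None = None
    n_summer_events: int = 11
    n_non_summer_events: int = 8
    # bundling
    window_days: int = 7
    f_hourly: bool = False
    # SOM
    candidates: tuple = som.DEFAULT_CANDIDATES
    seeds_per_size: int = 5
    epochs: int = 100
    run_scan: bool = True
    map_size: tuple[int, int] = (3, 3)       # used when run_scan is False
    convergence_repeats: int = 5
    smc_threshold: float = 0.9
    # typing
    kill_neuron_quantile: float = 0.75
    late_day_min: int = 6
    summer_months: tuple = (6, 7, 8, 9)
    rain_threshold: float = 0.1
    # risk
    alpha: float = 0.05
    baseline_windows: int | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["candidates"] = [list(c) for c in self.candidates]
        d["map_size"] = list(self.map_size)
        d["summer_months"] = list(self.summer_months)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "candidates" in d:
            d["candidates"] = tuple(tuple(c) for c in d["candidates"])
        if "map_size" in d:
            d["map_size"] = tuple(d["map_size"])
        if "summer_months" in d:
            d["summer_months"] = tuple(d["summer_months"])
        if "station_paths" in d and d["station_paths"] is not None:
            d["station_paths"] = dict(d["station_paths"])
        return cls(**d)


def stage_seeds(master_seed: int, n: int = len(_STAGES)) -> dict[str, int]:
    """Derive one sub-seed per stage from the master seed (SeedSequence spawn)."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return {name: int(c.generate_state(1)[0] % 2**31)
            for name, c in zip(_STAGES, children)}


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage and write artifacts + manifest under ``outdir``.

    Returns the manifest dict (stage -> {artifact name -> path}) augmented
    with in-memory results under the "results" key.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {"stages": {}, "seed": config.seed}
    results: dict = {}

    def record(stage: str, name: str, path: Path):
        manifest["stages"].setdefault(stage, {})[name] = str(path)

    # -- simulate (or load) -------------------------------------------------
    if config.station_paths:
        stations = {sid: io.read_station_csv(p, sid)
                    for sid, p in config.station_paths.items()}
        events = io.read_events_csv(config.events_path)
    else:
        stations, events = synthetic.simulate_study(
            seed=seeds["simulate"],
            n_summer=config.n_summer_events,
            n_non_summer=config.n_non_summer_events,
        )
    included = [e for e in events if not e.excluded]
    if not included:
        raise ValueError("no included events; nothing to analyze")
    for sid, series in stations.items():
        path = outdir / f"station_{sid}.csv"
        io.write_station_csv(series, path)
        record("simulate", sid, path)
    events_path = outdir / "events.csv"
    io.write_events_csv(events, events_path)
    record("simulate", "events", events_path)
    logger.info("simulate: %d stations, %d events (%d included)",
                len(stations), len(events), len(included))

    # -- interpolate + bundle + normalize -----------------------------------
    stations = {sid: preprocess.interpolate_missing(s)
                for sid, s in stations.items()}
    matrix = preprocess.bundle_events(stations, events,
                                      window_days=config.window_days,
                                      f_hourly=config.f_hourly)
    matrix = preprocess.normalize(matrix)
    bundled_path = outdir / "bundled.csv"
    io.write_bundled_csv(matrix, bundled_path)
    record("bundle", "bundled", bundled_path)
    logger.info("bundle: %d records (%d events x %d hours)",
                matrix.n, len(included), config.window_days * 24)

    # -- scan/train + convergence -------------------------------------------
    data = matrix.values()
    if config.run_scan:
        scan = som.scan_map_sizes(data, config.candidates,
                                  seeds_per_size=config.seeds_per_size,
                                  seed=seeds["train"], epochs=config.epochs)
        size = scan.selected
        scan_path = outdir / "scan.json"
        io.write_scan_json(scan, scan_path)
        record("train", "scan", scan_path)
        results["scan"] = scan
    else:
        size = config.map_size
    mean_smc, converged, _ = som.check_convergence(
        data, size, n_repeats=config.convergence_repeats,
        seed=seeds["train"] + 1, threshold=config.smc_threshold,
        epochs=config.epochs,
    )
    grid = som.train(
        som.init_grid(*size, d=data.shape[1], seed=seeds["train"],
                      epochs=config.epochs),
        data,
    )
    assignment = som.assign(grid, data)
    planes_path = outdir / "component_planes.csv"
    io.write_component_planes(grid, matrix, planes_path)
    record("train", "component_planes", planes_path)
    logger.info("train: map %dx%d, QE=%.4f TE=%.4f, mean SMC=%.3f (%s)",
                size[0], size[1],
                som.quantization_error(grid, data),
                som.topographic_error(grid, data),
                mean_smc, "converged" if converged else "NOT converged")

    # -- classify ------------------------------------------------------------
    kill_neurons = classify.identify_kill_neurons(
        assignment, matrix, quantile=config.kill_neuron_quantile)
    labels = classify.label_event_types(
        kill_neurons, assignment, matrix, events,
        summer_months=frozenset(config.summer_months),
        late_day_min=config.late_day_min)
    summaries = classify.neuron_summaries(assignment, matrix,
                                          rain_threshold=config.rain_threshold)
    summaries_path = outdir / "neuron_summaries.csv"
    summaries.to_csv(summaries_path)
    record("classify", "neuron_summaries", summaries_path)
    labels_path = outdir / "kill_types.csv"
    with open(labels_path, "w") as fh:
        fh.write("event_id,neuron,type\n")
        for lab in labels:
            neuron = "" if lab.neuron is None else lab.neuron
            fh.write(f"{lab.event_id},{neuron},{lab.kill_type}\n")
    record("classify", "kill_types", labels_path)
    logger.info("classify: kill neurons %s; %d events labeled",
                kill_neurons, len(labels))

    # -- risk: baselines, tests, thresholds, warnings ------------------------
    profiles = risk.baseline_profiles(
        stations, events, seed=seeds["risk"],
        n_windows=config.baseline_windows)
    tables = {season: risk.threshold_table(p)
              for season, p in profiles.items()}
    thresholds_path = outdir / "thresholds.csv"
    io.write_threshold_csv(tables, thresholds_path)
    record("risk", "thresholds", thresholds_path)

    # hourly significance per kill type, against the matching season baseline
    sig_rows = []
    type_events: dict[str, list] = {}
    for lab in labels:
        if lab.kill_type in ("summer", "non_summer"):
            ev = next(e for e in included if e.event_id == lab.event_id)
            type_events.setdefault(lab.kill_type, []).append(ev)
    station_of = {e.event_id: stations[e.station_id] for e in included}
    baseline_stacks: dict[str, dict] = {}
    for season, profile in profiles.items():
        # re-sample the baseline windows used for the profile
        ends_by_station = {
            sid: risk.sample_baseline_windows(series, events,
                                              seed=seeds["risk"] + k)
            for k, (sid, series) in enumerate(sorted(stations.items()))
        }
        stacks = {v: [] for v in risk.RISK_VARIABLES}
        for sid, series in sorted(stations.items()):
            for end in ends_by_station[sid]:
                if risk.season_of(end.month) != season:
                    continue
                win = risk.extract_window(series, end)
                for v in risk.RISK_VARIABLES:
                    stacks[v].append(win[v].to_numpy())
        baseline_stacks[season] = {v: np.asarray(a) for v, a in stacks.items()}
    significance = {}
    for kill_type, evs in type_events.items():
        if len(evs) < 2:
            continue
        kill_stack = {v: [] for v in risk.RISK_VARIABLES}
        for e in evs:
            win = risk.extract_window(station_of[e.event_id], e.reported_date)
            for v in risk.RISK_VARIABLES:
                kill_stack[v].append(win[v].to_numpy())
        kill_stack = {v: np.asarray(a) for v, a in kill_stack.items()}
        base = baseline_stacks.get(kill_type)
        if base is None or min(len(a) for a in base.values()) < 2:
            continue
        sig = risk.hourly_tests(kill_stack, base, alpha=config.alpha,
                                kill_type=kill_type)
        significance[kill_type] = sig
        for v in risk.RISK_VARIABLES:
            for hour, p in sig.p[v].items():
                sig_rows.append((kill_type, v, hour, p))
    sig_path = outdir / "significance.csv"
    with open(sig_path, "w") as fh:
        fh.write("type,variable,hour,p\n")
        for row in sig_rows:
            fh.write(f"{row[0]},{row[1]},{row[2]},{row[3]:.6g}\n")
    record("risk", "significance", sig_path)

    # evaluate each kill window against its season's thresholds
    warnings_by_event = {}
    for e in included:
        season = risk.season_of(e.reported_date.month)
        if season not in tables:
            continue
        win = risk.extract_window(station_of[e.event_id], e.reported_date)
        warnings_by_event[e.event_id] = risk.evaluate_warnings(
            win, tables[season])
    warn_path = outdir / "warnings.jsonl"
    io.write_warnings_jsonl(warnings_by_event, warn_path)
    record("risk", "warnings", warn_path)
    logger.info("risk: %d threshold tables, %d significance series, "
                "%d windows evaluated", len(tables), len(significance),
                len(warnings_by_event))

    # -- manifest + resolved config ------------------------------------------
    config_path = outdir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config.to_dict()))
    manifest["config"] = str(config_path)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))

    results.update({
        "matrix": matrix, "grid": grid, "assignment": assignment,
        "kill_neurons": kill_neurons, "labels": labels,
        "summaries": summaries, "profiles": profiles, "tables": tables,
        "significance": significance, "warnings": warnings_by_event,
        "mean_smc": mean_smc, "converged": converged, "size": size,
    })
    manifest["results"] = results
    return manifest
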