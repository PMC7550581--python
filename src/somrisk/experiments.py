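"""Study-scale computations on the synthetic system.

Each function here runs one of the package's headline checks at its study
size and returns plain numbers: the bundling count, SOM oracle agreement,
map-size recovery on planted prototypes, kill-type recovery, test
calibration and power, threshold recovery and warning detection.  They are
shared by the test suite and by ``scripts/acceptance.py`` so that both
report the same computations.

Seeds: every function takes a single integer seed and derives any internal
streams from it; results are deterministic given the seed (up to the
stochasticity the quantity itself measures).
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd

from . import classify, preprocess, risk, som, synthetic


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# bundling

def bundled_study(seed: int):
    """Simulate the default 19-event study; returns (matrix, events, stations)."""
    stations, events = synthetic.simulate_study(seed=seed)
    matrix = preprocess.normalize(preprocess.bundle_events(stations, events))
    return matrix, events, stations


def bundling_count(seed: int) -> int:
    """Number of bundled records for the default 19-event study."""
    matrix, _, _ = bundled_study(seed)
    return matrix.n


# ---------------------------------------------------------------------------
# planted prototypes for the map-size scan

def planted_prototypes(seed: int, n_per: int = 20, jitter: float = 0.03,
                       d: int = 6) -> np.ndarray:
    """Nine well-separated prototype patterns on a 3x3 grid.

    Prototypes sit at the grid points {0, 0.5, 1}^2 in the first two
    dimensions, 0.5 elsewhere, with Gaussian jitter of SD ``jitter`` —
    a configuration whose topology-consistent map is 3x3.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    for gx in (0.0, 0.5, 1.0):
        for gy in (0.0, 0.5, 1.0):
            proto = np.full(d, 0.5)
            proto[0], proto[1] = gx, gy
            blocks.append(proto + rng.normal(0.0, jitter, size=(n_per, d)))
    return np.clip(np.concatenate(blocks), 0.0, 1.0)


def scan_selection_rate(seed: int, n_reps: int = 20,
                        target: tuple[int, int] = (3, 3)) -> float:
    """Fraction of scan repetitions selecting ``target`` on planted data."""
    seeds = _spawn(seed, n_reps)
    hits = 0
    for s in seeds:
        data = planted_prototypes(s)
        scan = som.scan_map_sizes(data, seeds_per_size=5, seed=s + 1)
        hits += scan.selected == target
    return hits / n_reps


def qe_size_curve(seed: int, n_records: int = 1200,
                  seeds_per_size: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Mean QE and TE per candidate size on a fixed bundled-study subsample."""
    matrix, _, _ = bundled_study(seed)
    rng = np.random.default_rng(seed + 1)
    data = matrix.values()
    idx = rng.choice(len(data), size=min(n_records, len(data)), replace=False)
    scan = som.scan_map_sizes(data[idx], seeds_per_size=seeds_per_size,
                              seed=seed + 2)
    return scan.qe_mean, scan.te_mean


# ---------------------------------------------------------------------------
# kill typing

def kill_type_recovery(seed: int, n_seeds: int = 20) -> float:
    """Mean fraction of events labeled with their injected type.

    Each repetition simulates the 11-summer + 8-non-summer study, trains a
    3x3 map on the 3192-record matrix, identifies kill neurons and labels
    events; unclassified events count as misses.
    """
    accs = []
    for s in _spawn(seed, n_seeds):
        stations, events = synthetic.simulate_study(seed=s)
        matrix = preprocess.normalize(preprocess.bundle_events(stations, events))
        data = matrix.values()
        grid = som.train(som.init_grid(3, 3, data.shape[1], seed=s + 1), data)
        assignment = som.assign(grid, data)
        kill_neurons = classify.identify_kill_neurons(assignment, matrix)
        labels = classify.label_event_types(kill_neurons, assignment,
                                            matrix, events)
        truth = {e.event_id: e.kill_type for e in events}
        accs.append(np.mean([lab.kill_type == truth[lab.event_id]
                             for lab in labels]))
    return float(np.mean(accs))


def convergence_smc(seed: int) -> float:
    """Mean pairwise SMC over repeated 3x3 trainings of the default study."""
    matrix, _, _ = bundled_study(seed)
    mean, _, _ = som.check_convergence(matrix.values(), (3, 3),
                                       n_repeats=5, seed=seed + 1)
    return mean


# ---------------------------------------------------------------------------
# risk calibration

def _gaussian_windows(rng, n_windows, mean, sd, n_hours=168):
    return mean + sd * rng.standard_normal((n_windows, n_hours))


def type1_error(seed: int, n_reps: int = 200, n_kill: int = 11,
                n_base: int = 30, alpha: float = 0.05) -> float:
    """Fraction of hourly tests rejecting under the null.

    Kill and baseline windows are drawn from the same per-hour Gaussian;
    the rejection fraction is pooled over replicates and variables.
    """
    rng = np.random.default_rng(seed)
    rates = []
    for _ in range(n_reps):
        kill = {v: _gaussian_windows(rng, n_kill, 0.0, 1.0)
                for v in risk.RISK_VARIABLES}
        base = {v: _gaussian_windows(rng, n_base, 0.0, 1.0)
                for v in risk.RISK_VARIABLES}
        sig = risk.hourly_tests(kill, base, alpha=alpha)
        rates.append(sig.frac_significant.mean())
    return float(np.mean(rates))


def shift_power(seed: int, shift_sd: float = 1.0, n_kill: int = 11,
                n_base: int = 30, alpha: float = 0.05) -> dict[str, float]:
    """Fraction of hours flagged per variable when only T is shifted +1 SD."""
    rng = np.random.default_rng(seed)
    kill = {v: _gaussian_windows(rng, n_kill, 0.0, 1.0)
            for v in risk.RISK_VARIABLES}
    kill["T"] = kill["T"] + shift_sd
    base = {v: _gaussian_windows(rng, n_base, 0.0, 1.0)
            for v in risk.RISK_VARIABLES}
    sig = risk.hourly_tests(kill, base, alpha=alpha)
    return {v: float(sig.frac_significant[v]) for v in risk.RISK_VARIABLES}


def threshold_recovery_error(seed: int, n_windows: int = 50) -> dict[str, float]:
    """Max absolute error of threshold-table entries vs analytic bounds.

    Builds a baseline from ``n_windows`` windows drawn from known per-slot
    Gaussians (diurnal temperature cycle, constant AP/WS, dry R), then
    compares every table entry with the closed-form value from the true
    slot means and SDs.  Returns per-variable max errors in native units
    and the 3-SE tolerance actually allowed.
    """
    rng = np.random.default_rng(seed)
    hours = np.arange(168)
    hod = hours % 24
    # realistic diurnal structure: semidiurnal pressure tide, afternoon
    # temperature/wind maxima, afternoon convective rain peak
    true_mean = {
        "AP": 1003.0 + 1.5 * np.cos(2 * np.pi * (hod - 10) / 12.0),
        "T": 29.0 + 3.0 * np.cos(2 * np.pi * (hod - 14) / 24.0),
        "WS": 2.0 + 1.0 * np.cos(2 * np.pi * (hod - 15) / 24.0),
        "R": 0.2 + 0.15 * np.cos(2 * np.pi * (hod - 16) / 24.0),
    }
    true_sd = {"AP": 2.0, "T": 1.5, "WS": 0.8, "R": 0.3}
    windows = {v: true_mean[v] + true_sd[v]
               * rng.standard_normal((n_windows, 168))
               for v in risk.RISK_VARIABLES}
    mean = pd.DataFrame({v: windows[v].mean(axis=0)
                         for v in risk.RISK_VARIABLES},
                        index=pd.RangeIndex(1, 169, name="window_hour"))
    sd = pd.DataFrame({v: windows[v].std(axis=0, ddof=1)
                       for v in risk.RISK_VARIABLES}, index=mean.index)
    profile = risk.BaselineProfile("summer", mean, sd, n_windows)
    table = risk.threshold_table(profile).table

    day = hours // 24 + 1
    errors = {}
    for v, kind in (("AP", "min"), ("WS", "min"), ("T", "max"), ("R", "max")):
        err = 0.0
        for d in range(1, 8):
            mu = true_mean[v][day == d]
            if kind == "min":
                exp_norm, exp_1sd = mu.min(), (mu - true_sd[v]).min()
                got_norm = table.loc[d, f"{v}_min_normal"]
                got_1sd = table.loc[d, f"{v}_min_minus1sd"]
            else:
                exp_norm, exp_1sd = mu.max(), (mu + true_sd[v]).max()
                got_norm = table.loc[d, f"{v}_max_normal"]
                got_1sd = table.loc[d, f"{v}_max_plus1sd"]
            err = max(err, abs(got_norm - exp_norm), abs(got_1sd - exp_1sd))
        errors[v] = float(err)
        # combined SE of (slot mean - slot SD) at n windows
        se = true_sd[v] * np.sqrt(1.0 / n_windows + 1.0 / (2 * (n_windows - 1)))
        errors[f"{v}_tol"] = float(3.0 * se)
    return errors


def warning_detection(seed: int, n_reps: int = 50) -> tuple[float, bool]:
    """(fraction of injected summer windows with an action day,
    baseline-mean window stays quiet).

    The threshold table comes from one clean simulated summer season; each
    replicate injects the default summer signature into a fresh 10-day
    summer series and evaluates its final 7-day window.
    """
    seeds = _spawn(seed, n_reps + 1)
    base_series = synthetic.simulate_station(
        synthetic.SUMMER, n_days=122, start_date=date(2017, 6, 1),
        seed=seeds[-1], station_id="BASE")
    profile = risk.baseline_profiles({"BASE": base_series}, [],
                                     seed=seed)["summer"]
    table = risk.threshold_table(profile)
    hits = 0
    for s in seeds[:n_reps]:
        series = synthetic.simulate_station(
            synthetic.SUMMER, n_days=10, start_date=date(2018, 6, 1), seed=s)
        series, _ = synthetic.inject_kill_signature(
            series, date(2018, 6, 10), synthetic.SUMMER_KILL)
        window = risk.extract_window(series, date(2018, 6, 10))
        states = risk.evaluate_warnings(window, table)
        hits += any(st.level == "action" for st in states)
    quiet = all(
        st.level == "none"
        for st in risk.evaluate_warnings(profile.mean.copy(), table)
    )
    return hits / n_reps, quiet
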