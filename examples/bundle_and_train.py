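"""Bundle the 19-event synthetic study and pick a map size.

Bundles every kill event with its 7-day hourly window (19 x 7 x 24 = 3192
records of AP, T, WY, WX, R, F), min-max normalizes, scans candidate map
sizes 2x2..5x5 by QE/TE, and trains the selected map.  QE is the mean
record-to-BMU distance (map fit); TE the fraction of records whose
second-best neuron is not adjacent to the best (topology preservation).
"""

import somrisk as sr

stations, events = sr.simulate_study(seed=1)
matrix = sr.normalize(sr.bundle_events(stations, events))
print(f"bundled {len(matrix.event_ids)} events -> {matrix.n} records "
      f"x {matrix.normalized.shape[1]} variables")

data = matrix.values()
scan = sr.scan_map_sizes(data, seeds_per_size=5, seed=2)
for (r, c), qe, te in zip(scan.candidates, scan.qe_mean, scan.te_mean):
    marker = " <- selected" if (r, c) == scan.selected else ""
    print(f"  {r}x{c}: QE={qe:.3f} TE={te:.3f}{marker}")

grid = sr.train(sr.init_grid(*scan.selected, d=data.shape[1], seed=3), data)
print(f"trained {scan.selected[0]}x{scan.selected[1]} map: "
      f"QE={sr.quantization_error(grid, data):.3f} "
      f"TE={sr.topographic_error(grid, data):.4f}")
mean_smc, converged, _ = sr.check_convergence(data, scan.selected,
                                              n_repeats=5, seed=4)
print(f"run-to-run mean SMC {mean_smc:.3f} "
      f"({'converged' if converged else 'not converged'} at 0.9)")
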