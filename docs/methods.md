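# Methods

This note documents the models, defaults and design choices behind
`somrisk`, and what the synthetic experiments do and do not demonstrate.

## Synthetic weather generator

The generator (`somrisk.synthetic`) emulates the structure of hourly
records from subtropical river-basin weather stations.  Two seasonal
regimes are built in as defaults:

| parameter | summer | non-summer | units |
|---|---|---|---|
| AP mean / SD | 1003 / 2.0 | 1010 / 2.0 | hPa |
| T mean / SD / diurnal amplitude | 29 / 1.5 / 3.0 | 23 / 1.5 / 2.0 | °C |
| WS mean / SD | 2.0 / 0.8 | 2.0 / 0.8 | m/s |
| wind direction regime | diurnal rotation | constant NE (45° ± 10°) | — |
| storm rate / intensity mean | 0.5 /day, 1.0 | 0.7 /day, 0.8 | mm/h |
| AR(1) coefficient | 0.8 | 0.8 | — |

The seasonal contrast (≈7 hPa pressure, ≈6 °C temperature) straddles the
summer/non-summer separation typical of the climate the package targets;
wind regimes mirror the rotating summer breeze vs. steady winter monsoon
contrast.  Noise is AR(1) per channel with the *marginal* SD given above
(coefficient 0.8 for hourly persistence); temperature adds a cosine
diurnal cycle peaking at 14:00 local time (both the peak hour and the
implicit local-time convention are config).  Rain is a marked memoryless
process: Bernoulli hourly onsets at rate/24, fixed 3-hour storm duration,
i.i.d. exponential hourly intensities.  This is the simplest storm model
with a tunable rate and intensity; it makes no claim to convective realism.

Kill signatures perturb exactly one 168-hour window: per-day AP/T offsets,
per-day WS multipliers and added rainfall on boosted days.  The summer
default sags pressure through the week (−1…−3 hPa), raises temperature
(+1…+2 °C), damps mid-week wind and adds 1.8 mm/h of rain on days 5–7; the
non-summer default drops pressure early, raises temperature slightly on
days 1–3, cuts wind to 30 % on days 3–6 and adds storms on days 3–4 and 6.
These anomaly shapes encode the two observed pre-kill patterns (late
concentrated summer storms; early pressure drop with becalmed wind and
mid-window storms otherwise).

The default study simulates one kill station per regime (11 summer events
spaced 9 days apart Jun–Sep; 8 non-summer events spaced 7 days apart
Apr–May, so kill windows never overlap) plus one clean reference station
per regime.  The reference stations stand in for the multi-year,
multi-station depth of real archives: with 11 kills in one 122-day season
almost no non-overlapping kill-free windows remain, which would starve the
baseline estimation in a way real data would not.

What the generator does **not** emulate: spatial correlation between
stations, typhoon dynamics, fronts, serially dependent storm clustering,
instrument drift, or any water-quality process.  Passing tests on this
system show the pipeline recovers planted structure under realistic noise
and persistence — not that real fish kills are predictable at these rates.

## Preprocessing

Gaps are filled by per-channel linear interpolation; wind direction is
interpolated on its unit-circle components and recomposed so a 350°→10°
gap passes through north.  Missing endpoints are an error (no
extrapolation).  Bundling emits 7×24 records per included event with
F_day = 1…7; events flagged as pollution-caused are skipped.  F is
day-resolution by default (constant within a day; an hourly-resolution
variant is config).  Normalization is min–max per variable over the full
bundled matrix (not per event); stored min/max make denormalization exact,
and a zero-range column maps to the uninformative constant 0.5.  The wind
convention treats WD as the bearing in degrees, applied literally as
WY = WS·cos(WD), WX = WS·sin(WD); whether direction is "from" or "toward"
is a labeling choice that does not affect the clustering.

## Self-organizing map

Hexagonal odd-row-offset lattice: neuron (r, c) sits at
(c + 0.5·(r mod 2), r·√3/2); lattice distance is Euclidean between
centers and adjacency is distance ≤ 1 + 1e−9, giving interior neurons six
neighbors.  Weights initialize uniformly in the per-dimension data range.
Training is sequential: per presented record, the BMU (ties to the lowest
index) and a Gaussian neighborhood update with learning rate α: 0.5 → 0.01
and radius σ: max(rows, cols)/2 → 0.5, both decaying linearly over 100
epochs (all config).  The presentation order is a seeded shuffle of a
content-canonical (lexsorted) row ordering, so permuting input rows cannot
change the result; training is bit-deterministic under the grid seed.  The
inner loop is JIT-compiled with numba when available, with an equivalent
pure-Python fallback (a test asserts agreement).

Diagnostics follow the standard definitions: QE is the mean Euclidean
record-to-BMU distance; TE the fraction of records whose second-matching
unit is not lattice-adjacent to the BMU; the SMC between two runs is the
fraction of agreeing cells in their n×n record-pair neighborhood matrices
(cell = 1 iff the two records share a BMU or sit in adjacent neurons).

**Map-size selection.**  Candidates 2×2, 3×2, 3×3, 4×3, 4×4, 5×4, 5×5 are
each trained over 5 seeds and judged on mean TE and QE.  The primary rule
takes local minima of TE, where a minimum must undercut its ordered
neighbors by more than 0.01 — without the tolerance, noise at the 1e−3
level on an essentially flat curve manufactures spurious minima.  TE is
genuinely uninformative on cleanly separable data: maps up to ~3×3 are
almost fully adjacent, so TE ≈ 0 for every candidate.  In that regime the
QE curve decides instead: the candidate at the QE knee (largest discrete
second difference), which is where adding neurons stops buying fit.  Ties
prefer square maps, then fewer neurons.  This joint QE/TE reading selects
3×3 on data planted with nine prototypes and a small (3×2 or 3×3) map on
the default study.

**Convergence.**  `check_convergence` trains n maps from derived seeds and
reports the mean pairwise SMC against a 0.9 default threshold.  Even
perfectly clustered data can score ~0.9 on a pair of runs when the two
maps arrange the clusters with a topological twist; the score measures
*assignment-neighborhood* stability, not weight identity.

## Kill typing

Kill neurons are those whose mean normalized F exceeds the 75th percentile
of per-neuron means (never empty: falls back to the max-F set, so exact
ties all qualify).  Each event attaches to the kill neuron holding the
plurality of its late-window (F_day ≥ 6) records; an event with no late
record in any kill neuron stays unclassified.  A kill neuron's group is
summer if most of its events were reported in June–September (config).
Neuron summaries report raw-unit means, wind speed recomposed as
√(WY²+WX²), total rain, and "duration of R": the number of distinct
window hour-slots (1–168) whose member-record mean rain exceeds
0.1 mm/h.  Duration has no unique published definition; this is one
defensible reading and the threshold is config.

## Risk engine

Baselines are per window-hour (1–168) means and SDs of AP, T, WS, R over
7-day windows whose end date falls in the season and which overlap no kill
window; sampled windows are mutually non-overlapping by default so the
hourly tests can treat them as independent (overlap can be enabled for
data-poor settings, with a logged caveat).  The kill-vs-baseline
comparison is an unequal-variance (Welch) two-sample t-test per
window-hour and variable, reported as raw p-values without multiplicity
correction (a correction hook exists but is off by default, matching the
raw per-hour presentation the method is built around); zero-variance
degenerate slots use the convention p = 1 for equal means, p = 0
otherwise.

Threshold tables reduce each day's 24 hour-slots to operational bounds:
minimum of slot means and of (mean − SD) for the low-side variables AP and
WS; maximum of slot means and of (mean + SD) for the high-side variables T
and R.  A day's variable "crosses" when the daily extreme passes the ±1 SD
bound (the normal-average bounds are reported for context only); one
crossing → warning, two or more → action.  Daily aggregation (min/max
within the day) matches the daily structure of the threshold table; an
hourly-resolution crossing rule is a config alternative.

## Problem sizes and numerical choices

The study-scale experiments (`somrisk.experiments`, shared by the test
suite and `scripts/acceptance.py`) use: the default 19-event study (3192
records) for bundling, typing (20 repetitions at 3×3, the square map the
selection prefers at this scale) and convergence; 9 planted prototypes ×
20 records for the map-size scan (20 repetitions × 5 seeds per size) — the
prototypes sit on a 3×3 grid in the first two feature dimensions so a 3×3
map is the topology-consistent answer; a 1200-record subsample of the
bundled matrix for the QE/size curve; 200 replicates of 11-vs-30 Gaussian
windows for test calibration; 50 windows from known per-slot Gaussians for
threshold recovery (with realistic diurnal structure — semidiurnal
pressure tide, afternoon wind and convective-rain peaks — so the daily
extremes are well identified and the min/max estimators are not dominated
by extreme-value bias); and 50 injected-window replicates for warning
detection.  All randomness flows from a single seed through
`numpy.random.SeedSequence` spawning.

Tolerances: oracle equality for QE/TE/BMU and group-by summaries is
asserted at 1e−12; normalization round-trips at 1e−9; threshold recovery
within 3 combined standard errors of (slot mean − slot SD) at the window
count used.  Ties everywhere break toward the lowest index; training
treats data outside [0, 1] as a warning, not an error.

## Known limitations

- The pipeline types events by neuron-group month majority; a season whose
  events genuinely split across neurons can be mislabeled on unlucky runs
  (observed as occasional sub-90 % single-run recovery; the 20-repetition
  mean stays above 95 %).
- TE-based selection is only informative once maps are large enough for
  non-adjacent neuron pairs to matter; the QE-knee fallback covers the
  small-map regime but inherits the usual arbitrariness of elbow rules.
- Baseline SDs from few windows are noisy; threshold tables built from a
  single synthetic season (≈14 windows) are operationally usable but wide.
- Warning thresholds are purely meteorological; the package deliberately
  contains no dissolved-oxygen model.
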