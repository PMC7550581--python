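"""Self-organizing map on a hexagonal lattice, with QE/TE/SMC diagnostics.

The map is a Kohonen SOM trained by sequential (online) competitive
learning with a Gaussian neighborhood over hexagonal lattice distance.
Model selection follows the quantization-error / topographic-error recipe:
train candidate map sizes (2x2, 3x2, 3x3, ... 5x5), locate local minima of
TE along the size-ordered candidates, and prefer square then smaller maps.
Run-to-run convergence is scored with the simple matching coefficient
(SMC) between record-pair neighborhood matrices.

Lattice geometry: odd-row offset layout; neuron (r, c) sits at
(c + 0.5*(r % 2), r*sqrt(3)/2), so lattice neighbors are exactly the
neurons at unit distance and every interior neuron has six of them.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None

#: map sizes scanned for model selection, ordered by neuron count
DEFAULT_CANDIDATES = ((2, 2), (3, 2), (3, 3), (4, 3), (4, 4), (5, 4), (5, 5))

_ADJ_TOL = 1e-9


def hex_coords(rows: int, cols: int) -> np.ndarray:
    """Planar centers of an odd-row-offset hexagonal grid, row-major."""
    r, c = np.divmod(np.arange(rows * cols), cols)
    x = c + 0.5 * (r % 2)
    y = r * (np.sqrt(3.0) / 2.0)
    return np.column_stack([x, y]).astype(float)


def lattice_distances(rows: int, cols: int) -> np.ndarray:
    """Pairwise Euclidean distances between hexagonal lattice centers."""
    xy = hex_coords(rows, cols)
    diff = xy[:, None, :] - xy[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def adjacency(rows: int, cols: int) -> np.ndarray:
    """Boolean neuron-pair matrix: same neuron or lattice neighbors.

    Entry (i, j) is True iff i == j or neurons i and j are adjacent on the
    hexagonal lattice (unit center distance); symmetric, diagonal True.
    """
    return lattice_distances(rows, cols) <= 1.0 + _ADJ_TOL


@dataclass
class SOMGrid:
    """Hexagonal SOM: lattice shape, weights and training hyperparameters."""

    rows: int
    cols: int
    weights: np.ndarray          # (rows*cols, d)
    seed: int
    epochs: int = 100
    alpha: tuple[float, float] = (0.5, 0.01)     # initial, final learning rate
    sigma: tuple[float, float] | None = None     # neighborhood radius; default
                                                 # max(rows, cols)/2 -> 0.5

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != self.rows * self.cols:
            raise ValueError("weights do not match lattice size")
        if self.sigma is None:
            self.sigma = (max(self.rows, self.cols) / 2.0, 0.5)

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    @property
    def d(self) -> int:
        return self.weights.shape[1]

    @property
    def coords(self) -> np.ndarray:
        return hex_coords(self.rows, self.cols)

    @property
    def lattice_d2(self) -> np.ndarray:
        return lattice_distances(self.rows, self.cols) ** 2

    @property
    def adjacency(self) -> np.ndarray:
        return adjacency(self.rows, self.cols)


@dataclass
class Assignment:
    """Per-record BMU/SMU indices and quantization distances on one grid."""

    grid: SOMGrid
    bmu: np.ndarray     # (n,) int
    smu: np.ndarray     # (n,) int
    qdist: np.ndarray   # (n,) float, ||x_i - u_bmu||

    @property
    def n(self) -> int:
        return len(self.bmu)


def init_grid(
    rows: int,
    cols: int,
    d: int,
    seed: int,
    data_range: tuple[np.ndarray, np.ndarray] | None = None,
    **hyper,
) -> SOMGrid:
    """Random grid with weights uniform within the per-dimension data range
    (unit cube by default); deterministic under a fixed seed."""
    if rows < 1 or cols < 1 or d < 1:
        raise ValueError("rows, cols and d must be >= 1")
    rng = np.random.default_rng(seed)
    if data_range is None:
        lo, hi = np.zeros(d), np.ones(d)
    else:
        lo, hi = (np.asarray(a, dtype=float) for a in data_range)
    weights = rng.uniform(lo, hi, size=(rows * cols, d))
    return SOMGrid(rows=rows, cols=cols, weights=weights, seed=seed, **hyper)


def find_bmu(grid: SOMGrid, x: np.ndarray) -> tuple[int, int, float]:
    """Best- and second-matching units for one record.

    Ties broken toward the lowest neuron index (stable sort).  Requires at
    least two neurons for the SMU to exist.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (grid.d,):
        raise ValueError(f"expected a vector of length {grid.d}")
    dist = np.sqrt(((grid.weights - x) ** 2).sum(axis=1))
    order = np.argsort(dist, kind="stable")
    bmu = int(order[0])
    smu = int(order[1]) if grid.n_neurons > 1 else -1
    return bmu, smu, float(dist[bmu])


def assign(grid: SOMGrid, data: np.ndarray) -> Assignment:
    """Vectorized BMU/SMU assignment for a whole data matrix."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[1] != grid.d:
        raise ValueError("data dimension does not match grid")
    d2 = ((data[:, None, :] - grid.weights[None, :, :]) ** 2).sum(axis=2)
    bmu = d2.argmin(axis=1)
    qdist = np.sqrt(d2[np.arange(len(data)), bmu])
    if grid.n_neurons > 1:
        d2[np.arange(len(data)), bmu] = np.inf
        smu = d2.argmin(axis=1)
    else:
        smu = np.full(len(data), -1)
    return Assignment(grid=grid, bmu=bmu, smu=smu, qdist=qdist)


def _train_loop(weights, data, order, lat_d2, alphas, sigmas):
    """Sequential SOM updates; ``order`` is (epochs, n) presentation indices."""
    m = weights.shape[0]
    for e in range(order.shape[0]):
        alpha = alphas[e]
        two_s2 = 2.0 * sigmas[e] * sigmas[e]
        for k in range(order.shape[1]):
            x = data[order[e, k]]
            best = 0
            best_d = np.inf
            for j in range(m):
                dd = 0.0
                for v in range(weights.shape[1]):
                    diff = weights[j, v] - x[v]
                    dd += diff * diff
                if dd < best_d:
                    best_d = dd
                    best = j
            for j in range(m):
                h = alpha * np.exp(-lat_d2[j, best] / two_s2)
                for v in range(weights.shape[1]):
                    weights[j, v] += h * (x[v] - weights[j, v])
    return weights


_train_loop_py = _train_loop
if njit is not None:
    _train_loop = njit(cache=False)(_train_loop)


def _schedules(grid: SOMGrid, epochs: int) -> tuple[np.ndarray, np.ndarray]:
    a0, a1 = grid.alpha
    s0, s1 = grid.sigma
    if epochs == 1:
        return np.array([a0]), np.array([s0])
    t = np.arange(epochs) / (epochs - 1)
    return a0 + (a1 - a0) * t, s0 + (s1 - s0) * t


def train(grid: SOMGrid, data: np.ndarray, epochs: int | None = None,
          _force_python: bool = False) -> SOMGrid:
    """Train a copy of ``grid`` by sequential competitive learning.

    Learning rate and neighborhood radius decay linearly over epochs.  The
    presentation order is a seeded shuffle of a content-canonical (lexsorted)
    ordering of the rows, so permuting the input rows does not change the
    trained weights.  Deterministic under the grid's seed.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[1] != grid.d:
        raise ValueError("data dimension does not match grid")
    if np.nanmin(data) < 0.0 or np.nanmax(data) > 1.0:
        warnings.warn("training data extend outside [0, 1]; normalize first",
                      stacklevel=2)
    n = len(data)
    if n < grid.n_neurons:
        warnings.warn(f"fewer records ({n}) than neurons ({grid.n_neurons})",
                      stacklevel=2)
    epochs = grid.epochs if epochs is None else epochs
    canonical = np.lexsort(data.T[::-1])  # row-content order, permutation-proof
    rng = np.random.default_rng(grid.seed)
    order = np.empty((epochs, n), dtype=np.int64)
    for e in range(epochs):
        order[e] = canonical[rng.permutation(n)]
    alphas, sigmas = _schedules(grid, epochs)
    loop = _train_loop_py if _force_python else _train_loop
    weights = loop(grid.weights.copy(), data, order, grid.lattice_d2,
                   alphas, sigmas)
    return replace(grid, weights=weights)


def quantization_error(grid: SOMGrid, data: np.ndarray) -> float:
    """QE: mean Euclidean distance from each record to its BMU weight."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if len(data) == 0:
        raise ValueError("QE undefined for empty data")
    return float(assign(grid, data).qdist.mean())


def topographic_error(grid: SOMGrid, data: np.ndarray) -> float:
    """TE: fraction of records whose SMU is not lattice-adjacent to the BMU."""
    if grid.n_neurons < 2:
        raise ValueError("TE undefined for a single-neuron map")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if len(data) == 0:
        raise ValueError("TE undefined for empty data")
    a = assign(grid, data)
    adj = grid.adjacency
    return float(np.mean(~adj[a.bmu, a.smu]))


def neighborhood_matrix(assignment: Assignment) -> np.ndarray:
    """n x n boolean matrix: records sharing or lattice-adjacent BMUs."""
    adj = assignment.grid.adjacency
    return adj[assignment.bmu][:, assignment.bmu]


def smc(assignment_a: Assignment, assignment_b: Assignment) -> float:
    """Simple matching coefficient between two runs' neighborhood matrices.

    Matches (cells where both matrices agree, whether 1-1 or 0-0) divided
    by n^2; 1.0 for identical assignments, symmetric in its arguments.
    """
    if assignment_a.n != assignment_b.n:
        raise ValueError("assignments cover different numbers of records")
    ma = neighborhood_matrix(assignment_a)
    mb = neighborhood_matrix(assignment_b)
    return float((ma == mb).mean())


@dataclass
class MapSizeScan:
    """QE/TE traces over candidate sizes and the selected map shape."""

    candidates: tuple[tuple[int, int], ...]
    qe_mean: np.ndarray          # per candidate, averaged over seeds
    te_mean: np.ndarray
    qe_runs: np.ndarray          # (n_candidates, seeds_per_size)
    te_runs: np.ndarray
    selected: tuple[int, int]
    local_minima: list[tuple[int, int]]

    def to_dict(self) -> dict:
        return {
            "candidates": [list(c) for c in self.candidates],
            "qe_mean": self.qe_mean.tolist(),
            "te_mean": self.te_mean.tolist(),
            "qe_runs": self.qe_runs.tolist(),
            "te_runs": self.te_runs.tolist(),
            "selected": list(self.selected),
            "local_minima": [list(c) for c in self.local_minima],
        }


def _shape_rank(c):
    rows, cols = c
    return (rows != cols, rows * cols)


def _select_size(candidates, te_mean, qe_mean, te_tol=0.01):
    """Model selection along the size-ordered candidates.

    Primary rule: local minima of mean TE, where a minimum must undercut
    its ordered neighbors by more than ``te_tol`` (endpoints qualify
    against their single neighbor).  When TE is flat to within the
    tolerance — which happens whenever the data are cleanly separable,
    because small hexagonal lattices are almost fully adjacent — the QE
    curve decides instead: the candidate at the knee (largest discrete
    second difference of QE) is taken.  Ties prefer square shapes, then
    fewer neurons.
    """
    k = len(candidates)
    minima = []
    for i in range(k):
        left_ok = i == 0 or te_mean[i] < te_mean[i - 1] - te_tol
        right_ok = i == k - 1 or te_mean[i] < te_mean[i + 1] - te_tol
        if left_ok and right_ok:
            minima.append(candidates[i])
    if not minima and k >= 3:
        curv = np.full(k, -np.inf)
        for i in range(1, k - 1):
            curv[i] = (qe_mean[i - 1] - qe_mean[i]) - (qe_mean[i] - qe_mean[i + 1])
        best = curv.max()
        minima = [candidates[i] for i in range(k)
                  if curv[i] >= best - 1e-12]
    if not minima:
        minima = list(candidates)
    selected = min(minima, key=_shape_rank)
    return minima, selected


def scan_map_sizes(
    data: np.ndarray,
    candidates: tuple[tuple[int, int], ...] = DEFAULT_CANDIDATES,
    seeds_per_size: int = 5,
    seed: int = 0,
    epochs: int | None = None,
    **hyper,
) -> MapSizeScan:
    """Train every candidate size over several seeds and select the map.

    QE/TE are averaged per size over ``seeds_per_size`` independent
    trainings; selection takes local minima of mean TE and prefers square
    then smaller maps (QE decreases monotonically with neuron count, so it
    guides but cannot select on its own).
    """
    if not candidates:
        raise ValueError("empty candidate list")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    counts = [r * c for r, c in candidates]
    if counts != sorted(counts):
        raise ValueError("candidates must be ordered by neuron count")
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % 2**31)
                 for s in ss.spawn(len(candidates) * seeds_per_size)]
    qe = np.empty((len(candidates), seeds_per_size))
    te = np.empty_like(qe)
    for i, (rows, cols) in enumerate(candidates):
        for j in range(seeds_per_size):
            g = init_grid(rows, cols, data.shape[1],
                          seed=run_seeds[i * seeds_per_size + j], **hyper)
            g = train(g, data, epochs=epochs)
            qe[i, j] = quantization_error(g, data)
            te[i, j] = topographic_error(g, data)
    qe_mean, te_mean = qe.mean(axis=1), te.mean(axis=1)
    minima, selected = _select_size(candidates, te_mean, qe_mean)
    return MapSizeScan(
        candidates=tuple(candidates), qe_mean=qe_mean, te_mean=te_mean,
        qe_runs=qe, te_runs=te, selected=selected, local_minima=minima,
    )


def check_convergence(
    data: np.ndarray,
    size: tuple[int, int],
    n_repeats: int = 5,
    seed: int = 0,
    threshold: float = 0.9,
    epochs: int | None = None,
    **hyper,
) -> tuple[float, bool, list[float]]:
    """Train ``n_repeats`` maps with derived seeds and score agreement.

    Returns (mean pairwise SMC, mean >= threshold, all pairwise SMCs).
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    rows, cols = size
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_repeats)]
    assignments = []
    for s in seeds:
        g = train(init_grid(rows, cols, data.shape[1], seed=s, **hyper),
                  data, epochs=epochs)
        assignments.append(assign(g, data))
    pairwise = [smc(a, b) for a, b in itertools.combinations(assignments, 2)]
    mean = float(np.mean(pairwise))
    return mean, mean >= threshold, pairwise
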