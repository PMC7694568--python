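"""The CA-Markov landscape simulator.

Each annual step couples the two model halves:

* the **Markov half** turns the current per-class cell counts into next-year
  *demands* via the transition matrix (largest-remainder rounding makes them
  whole cells that sum exactly to the dynamic-cell total);
* the **cellular-automaton half** allocates those demands spatially.  A
  cell's suitability for class *c* is the local frequency of *c* among
  dynamic cells in the centred ``filter_size x filter_size`` contiguity
  window (truncated at the frame edge, no wraparound) multiplied by the
  Markov probability of moving from the cell's current class to *c*.
  Demands are then claimed greedily over ``n_iterations`` rounds: each
  round every class takes its per-round share of demand from the unassigned
  cells where it scores highest, ties broken by a seeded RNG.

Static classes (water, roads, ponds) and nodata cells are copied unchanged.
After every step the per-class cell counts equal the rounded demands
exactly, so area bookkeeping is conserved by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .markov import TransitionMatrix
from .raster_io import LandscapeGrid

__all__ = ["SimulationConfig", "SuitabilityStack", "neighborhood_suitability",
           "step", "run", "largest_remainder_round"]


@dataclass(frozen=True)
class SimulationConfig:
    """CA-Markov step parameters.

    ``n_iterations`` is the number of allocation rounds *within* each
    annual step (the per-step claiming schedule), not a number of simulated
    years; the simulated span is the separate ``n_years`` argument of
    :func:`run`.
    """

    filter_size: int = 5
    n_iterations: int = 20
    seed: int = 0
    step_years: float = 1.0
    dynamic_codes: tuple[int, ...] | None = None  # default: scheme's dynamic set

    def __post_init__(self) -> None:
        if self.filter_size < 3 or self.filter_size % 2 == 0:
            raise ValueError(f"filter_size must be odd and >= 3, got {self.filter_size}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    def resolve_dynamic(self, grid: LandscapeGrid) -> list[int]:
        codes = (list(self.dynamic_codes) if self.dynamic_codes is not None
                 else grid.scheme.dynamic_codes)
        static = set(grid.scheme.codes) - set(codes)
        if set(codes) & static:
            raise ValueError("dynamic and static code sets overlap")
        return codes


@dataclass
class SuitabilityStack:
    """Per-dynamic-class suitability lattices in [0, 1]; 0 on static/nodata."""

    layers: dict[int, np.ndarray]

    def __getitem__(self, code: int) -> np.ndarray:
        return self.layers[code]


def _window_counts(indicator: np.ndarray, size: int) -> np.ndarray:
    kernel = np.ones((size, size))
    return ndimage.convolve(indicator.astype(float), kernel, mode="constant", cval=0.0)


def neighborhood_suitability(
    grid: LandscapeGrid,
    matrix: TransitionMatrix,
    config: SimulationConfig,
) -> SuitabilityStack:
    """Contiguity-filter suitability of every cell for every dynamic class.

    suitability(cell, c) = fraction of class c among dynamic cells in the
    centred window, times P[current class of cell -> c].  Windows truncate
    at the frame edge; static and nodata cells score 0 everywhere.
    """
    codes = config.resolve_dynamic(grid)
    v = grid.values
    dyn = np.isin(v, codes)
    den = _window_counts(dyn, config.filter_size)
    den_safe = np.where(den > 0, den, 1.0)

    layers: dict[int, np.ndarray] = {}
    # P[current -> c] looked up per cell through the code index map
    idx = np.full(v.shape, -1, dtype=np.int64)
    for i, c in enumerate(matrix.class_codes):
        idx[v == c] = i
    for c in codes:
        frac = _window_counts(dyn & (v == c), config.filter_size) / den_safe
        j = matrix.class_codes.index(c)
        p = np.zeros_like(frac)
        valid = idx >= 0
        p[valid] = matrix.probs[idx[valid], j]
        suit = frac * p
        suit[~dyn] = 0.0
        layers[c] = suit
    return SuitabilityStack(layers=layers)


def largest_remainder_round(fractions: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` whole units to ``fractions`` (which sum to ~total).

    Floors every share and hands the leftover units to the largest
    fractional remainders (ties: lowest index), conserving the total exactly.
    """
    fractions = np.asarray(fractions, dtype=float)
    scaled = fractions * (total / fractions.sum()) if fractions.sum() > 0 else fractions
    base = np.floor(scaled).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(scaled - base), kind="stable")
        base[order[:short]] += 1
    return base


def _integer_flows(counts: np.ndarray, P: np.ndarray, demand: np.ndarray) -> np.ndarray:
    """Integer transition flows F[i, j] ~ counts[i] * P[i, j].

    Row sums equal the current class counts and column sums equal the
    aggregate largest-remainder demands exactly (an integer transportation
    rounding): rows are rounded by largest remainder, then single units are
    shifted between columns of the rows that least disturb the real-valued
    flows until the column margins match.
    """
    k = len(counts)
    real = counts[:, None] * P
    F = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        if counts[i] > 0:
            F[i] = largest_remainder_round(real[i], int(counts[i]))
    diff = demand - F.sum(axis=0)  # sums to zero
    while diff.any():
        jp, jm = int(np.argmax(diff)), int(np.argmin(diff))
        rows = np.flatnonzero(F[:, jm] > 0)
        i = rows[int(np.argmax(real[rows, jp] - F[rows, jp]))]
        F[i, jm] -= 1
        F[i, jp] += 1
        diff[jp] -= 1
        diff[jm] += 1
    assert (F >= 0).all() and (F.sum(axis=1) == counts).all() \
        and (F.sum(axis=0) == demand).all()
    return F


def _split_quota(demand: int, n_rounds: int) -> np.ndarray:
    """Spread an integer demand over rounds as evenly as possible."""
    q = np.full(n_rounds, demand // n_rounds, dtype=np.int64)
    q[: demand % n_rounds] += 1
    return q


def step(
    grid: LandscapeGrid,
    matrix: TransitionMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> LandscapeGrid:
    """Advance the landscape by one Markov step with spatial allocation.

    Output per-class cell counts equal the largest-remainder-rounded Markov
    demands exactly; static and nodata cells pass through unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    codes = config.resolve_dynamic(grid)
    if set(codes) - set(matrix.class_codes):
        raise ValueError("dynamic codes missing from the transition matrix")
    v = grid.values
    dyn_mask = np.isin(v, codes)
    flat_idx = np.flatnonzero(dyn_mask.ravel())
    n_total = flat_idx.size
    if n_total == 0:
        return grid.with_values(v.copy(), date=grid.date + int(round(config.step_years)))

    # Markov demands from current counts
    counts = np.array([(v == c).sum() for c in codes], dtype=np.int64)
    P = matrix.probs / matrix.probs.sum(axis=1, keepdims=True)
    sel = [matrix.class_codes.index(c) for c in codes]
    block = P[np.ix_(sel, sel)]
    demand = largest_remainder_round(counts @ block, n_total)
    assert demand.sum() == n_total, "demand must exhaust the dynamic cells"
    flows = _integer_flows(counts, block, demand)

    # Iterative flow allocation: the Markov chain prescribes gross flows
    # (how many cells of source i become destination j), and each flow is
    # claimed from the source class's cells most suitable for the
    # destination.  Every round re-applies the contiguity filter to the
    # provisional landscape, so class fronts can propagate farther than one
    # filter radius within a single annual step.
    tiebreak = rng.random(n_total)
    assigned = np.zeros(n_total, dtype=bool)
    new_class = np.empty(n_total, dtype=np.int64)
    cur_flat = v.ravel()[flat_idx]
    k = len(codes)
    pairs = [(i, j) for i in range(k) for j in range(k)
             if i != j and flows[i, j] > 0]
    targets = {(i, j): np.cumsum(_split_quota(int(flows[i, j]), config.n_iterations))
               for i, j in pairs}
    claimed = {p: 0 for p in pairs}
    provisional = grid.with_values(v.copy())

    for rnd in range(config.n_iterations):
        stack = neighborhood_suitability(provisional, matrix, config)
        suits = {c: stack[c].ravel()[flat_idx] for c in codes}
        for pi in rng.permutation(len(pairs)):
            i, j = pairs[pi]
            want = int(targets[(i, j)][rnd]) - claimed[(i, j)]
            if want <= 0:
                continue
            suit = suits[codes[j]]
            cand = np.flatnonzero((cur_flat == codes[i]) & (suit > 0) & ~assigned)
            order = cand[np.lexsort((tiebreak[cand], -suit[cand]))]
            take = order[:want]
            assigned[take] = True
            new_class[take] = codes[j]
            claimed[(i, j)] += take.size
            provisional.values.ravel()[flat_idx[take]] = codes[j]
            # shortfall (no suitable source cells yet) rolls into later
            # rounds as the advancing front reaches new cells

    # leftover pass: flows that never found a positively suitable source
    # cell are forced onto the remaining source cells (random order) so the
    # accounting stays exact even on degenerate geometries
    for (i, j), got in claimed.items():
        short = int(flows[i, j]) - got
        if short > 0:
            cand = np.flatnonzero((cur_flat == codes[i]) & ~assigned)
            take = cand[rng.permutation(cand.size)[:short]]
            assigned[take] = True
            new_class[take] = codes[j]
            claimed[(i, j)] += short

    # cells no flow claimed keep their class (the diagonal of the flow matrix)
    keep = ~assigned
    new_class[keep] = cur_flat[keep]
    out = v.copy()
    out.ravel()[flat_idx] = new_class
    result = grid.with_values(out, date=grid.date + int(round(config.step_years)))
    for c, d in zip(codes, demand):
        got = int((result.values == c).sum())
        assert got == d, f"class {c}: allocated {got} cells, demanded {d}"
    return result


def run(
    grid: LandscapeGrid,
    matrix: TransitionMatrix,
    config: SimulationConfig,
    n_years: int,
) -> list[LandscapeGrid]:
    """Simulate ``n_years`` successive annual steps; deterministic per seed."""
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(config.seed)
    out: list[LandscapeGrid] = []
    current = grid
    for _ in range(n_years):
        current = step(current, matrix, config, rng=rng)
        out.append(current)
    return out
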