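"""Synthetic banded coastal landscapes and a ground-truth succession process.

The generator emulates the shore-parallel zonation of a silty intertidal
flat: belts ordered land -> sea as Phragmites australis -> Suaeda salsa ->
(optional Spartina alterniflora strip) -> mudflat, on 30 m cells, with
per-transect belt boundaries roughened by a clipped Gaussian random walk so
fronts are ragged but never inverted.

:func:`evolve` is the known-parameter forward process used for parameter
recovery: each year every dynamic cell redraws its class from
``(1 - w) * P[current -> .] + w * (local class frequencies)``.  At
``w = 0`` this is exactly the cell-independent Markov chain, so estimating
transitions on consecutive outputs must recover the generating matrix; at
``w > 0`` spatial contagion sharpens the fronts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import reference
from .ca import _window_counts
from .markov import TransitionMatrix
from .raster_io import ClassScheme, LandscapeGrid

__all__ = ["SyntheticConfig", "make_banded_grid", "evolve"]


def _default_matrix() -> TransitionMatrix:
    return reference.TRANSITION_1985_1990_ANNUAL


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition defaults for the synthetic landscape.

    The default frame is a 200 x 200 lattice of 30 m cells (3,600 ha, a
    scaled-down version of the ~23,830 ha study strip), belts sized to the
    observed 1985 landscape shares (P. australis ~21 %, S. salsa ~16 %,
    the rest mudflat), 2-cell boundary roughness, and annual transitions
    drawn from the published 1985-1990 matrix.
    """

    rows: int = 200
    cols: int = 200
    cell_size: float = 30.0
    band_fractions: tuple[float, float, float] = (0.21, 0.16, 0.63)  # P.a., S. salsa, mudflat
    invader_width: int = 0
    boundary_roughness: float = 2.0
    transition_matrix: TransitionMatrix = field(default_factory=_default_matrix)
    contagion_weight: float = 0.0
    seed: int = 0
    baseline_edge: str = "north"
    scheme: ClassScheme = reference.YANCHENG_SCHEME

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.band_fractions) or sum(self.band_fractions) > 1 + 1e-9:
            raise ValueError("band fractions must be positive and sum to <= 1")
        if self.boundary_roughness < 0:
            raise ValueError("boundary_roughness must be >= 0")
        if not 0.0 <= self.contagion_weight <= 1.0:
            raise ValueError("contagion_weight must lie in [0, 1]")
        if self.invader_width < 0:
            raise ValueError("invader_width must be >= 0")


def make_banded_grid(config: SyntheticConfig, date: int = 1985) -> LandscapeGrid:
    """Generate a shore-parallel banded landscape, deterministic per seed.

    Bands run land -> sea (baseline row outward): P. australis, S. salsa,
    optional S. alterniflora strip of ``invader_width`` cells, then mudflat;
    any depth beyond the stated fractions is open water.  Each inter-band
    boundary is jittered per transect by a seeded Gaussian random walk of
    standard deviation ``boundary_roughness`` cells, clipped so band order
    is preserved (no inversions).
    """
    rows, cols = config.rows, config.cols
    f_ph, f_su, f_mud = config.band_fractions
    depth_ph = round(f_ph * rows)
    depth_su = round((f_ph + f_su) * rows)
    depth_mud = round((f_ph + f_su + f_mud) * rows)
    if config.invader_width and depth_su + config.invader_width > depth_mud:
        raise ValueError("invader strip does not fit between S. salsa and mudflat")
    if depth_ph < 1 or depth_su > rows:
        raise ValueError("bands exceed grid depth")

    rng = np.random.default_rng(config.seed)

    def jitter(base: int) -> np.ndarray:
        if config.boundary_roughness == 0:
            return np.full(cols, base)
        walk = np.cumsum(rng.normal(0.0, config.boundary_roughness, size=cols))
        walk -= walk.mean()
        return np.clip(np.round(base + walk), 0, rows).astype(np.int64)

    b1 = jitter(depth_ph)                       # P. australis | S. salsa
    b2 = np.maximum(jitter(depth_su), b1)       # S. salsa | invader/mudflat
    b3 = np.minimum(b2 + config.invader_width, rows)
    b4 = np.maximum(jitter(depth_mud), b3)      # mudflat | water

    rr = np.arange(rows)[:, None]
    v = np.full((rows, cols), reference.WATER, dtype=np.int64)
    v[rr < b4[None, :]] = reference.MUDFLAT
    if config.invader_width:
        v[(rr >= b2[None, :]) & (rr < b3[None, :])] = reference.SPARTINA
    v[rr < b2[None, :]] = reference.SUAEDA
    v[rr < b1[None, :]] = reference.PHRAGMITES

    # canonical frame has the baseline on top; re-orient if asked otherwise
    if config.baseline_edge == "south":
        v = v[::-1, :]
    elif config.baseline_edge == "west":
        v = v.T.copy()
    elif config.baseline_edge == "east":
        v = v[::-1, :].T.copy()
    return LandscapeGrid(values=v, cell_size=config.cell_size, date=date,
                         scheme=config.scheme, baseline_edge=config.baseline_edge)


def evolve(
    grid: LandscapeGrid,
    config: SyntheticConfig,
    n_years: int,
    window: int = 5,
) -> list[LandscapeGrid]:
    """Forward-simulate annual cell transitions under known parameters.

    Per year, every dynamic cell's next class is drawn from the mixture
    ``(1 - w) * P[current -> .] + w * f_local`` where ``f_local`` are the
    class frequencies among dynamic cells in the centred ``window`` x
    ``window`` neighborhood and ``w`` is the contagion weight.  Static and
    nodata cells are frozen.  Deterministic per config seed.
    """
    matrix = config.transition_matrix
    codes = matrix.class_codes
    extra = set(np.unique(grid.values)) - set(codes) - set(grid.scheme.static_codes) \
        - {grid.scheme.nodata_code}
    if extra:
        raise ValueError(f"grid classes {sorted(extra)} not covered by the matrix or statics")
    P = matrix.probs
    w = config.contagion_weight
    rng = np.random.default_rng(config.seed + 1)  # offset: independent of band jitter

    out: list[LandscapeGrid] = []
    current = grid.values.copy()
    for year in range(1, n_years + 1):
        dyn = np.isin(current, codes)
        probs = np.zeros(current.shape + (len(codes),))
        if w > 0:
            den = _window_counts(dyn, window)
            den = np.where(den > 0, den, 1.0)
        for j, c in enumerate(codes):
            base = np.zeros(current.shape)
            for i, ci in enumerate(codes):
                base[current == ci] = P[i, j]
            if w > 0:
                local = _window_counts(dyn & (current == c), window) / den
                probs[..., j] = (1 - w) * base + w * local
            else:
                probs[..., j] = base
        # renormalize (mixture rows can drift by round-off; also frozen cells)
        tot = probs.sum(axis=-1)
        tot = np.where(tot > 0, tot, 1.0)
        probs /= tot[..., None]

        u = rng.random(current.shape)
        cum = np.cumsum(probs, axis=-1)
        choice = (u[..., None] > cum).sum(axis=-1)
        nxt = current.copy()
        code_arr = np.array(codes)
        nxt[dyn] = code_arr[np.clip(choice[dyn], 0, len(codes) - 1)]
        current = nxt
        out.append(grid.with_values(current.copy(), date=grid.date + year))
    return out
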