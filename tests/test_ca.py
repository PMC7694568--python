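"""CA-Markov simulator: suitability filter, demand accounting, determinism."""

import numpy as np
import pytest

from marshca import (SimulationConfig, TransitionMatrix,
                     neighborhood_suitability, run, step)
from marshca import reference as R
from marshca.ca import largest_remainder_round
from marshca.synthetic import SyntheticConfig, make_banded_grid

DYN = [R.SUAEDA, R.PHRAGMITES, R.MUDFLAT]
IDENTITY = TransitionMatrix(np.eye(3), DYN)
PUBLISHED = R.TRANSITION_1985_1990_ANNUAL


def brute_force_suitability(grid, matrix, code, size):
    """Naive double-loop window scan: the independent oracle for the filter."""
    v = grid.values
    dyn_codes = grid.scheme.dynamic_codes
    rows, cols = v.shape
    half = size // 2
    out = np.zeros((rows, cols))
    for r in range(rows):
        for c in range(cols):
            if v[r, c] not in dyn_codes:
                continue
            window = v[max(0, r - half): r + half + 1, max(0, c - half): c + half + 1]
            dyn = np.isin(window, dyn_codes)
            if dyn.sum() == 0:
                continue
            frac = (window[dyn] == code).mean()
            p = matrix.probs[matrix.class_codes.index(v[r, c]),
                             matrix.class_codes.index(code)]
            out[r, c] = frac * p
    return out


def naive_largest_remainder(fracs, total):
    """Oracle: sort-free apportionment by repeatedly granting max remainder."""
    scaled = np.asarray(fracs, float) * total / np.sum(fracs)
    base = [int(np.floor(x)) for x in scaled]
    rem = [x - b for x, b in zip(scaled, base)]
    for _ in range(total - sum(base)):
        i = max(range(len(rem)), key=lambda j: (rem[j], -j))
        base[i] += 1
        rem[i] = -1
    return np.array(base)


class TestSimulationConfig:
    def test_even_filter_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SimulationConfig(filter_size=4)

    def test_tiny_filter_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SimulationConfig(filter_size=1)


class TestNeighborhoodSuitability:
    def test_uniform_grid_interior_and_corner(self, grid_factory):
        g = grid_factory(np.full((9, 9), R.SUAEDA))
        stack = neighborhood_suitability(g, IDENTITY, SimulationConfig())
        # interior: full 5x5 window of the class; corner: truncated 3x3, still all c
        assert stack[R.SUAEDA][4, 4] == pytest.approx(1.0)
        assert stack[R.SUAEDA][0, 0] == pytest.approx(1.0)
        assert stack[R.PHRAGMITES][4, 4] == 0.0

    def test_single_cell_center_fraction(self, grid_factory):
        v = np.full((7, 7), R.MUDFLAT)
        v[3, 3] = R.SUAEDA
        g = grid_factory(v)
        stack = neighborhood_suitability(g, IDENTITY, SimulationConfig())
        # the lone S. salsa cell sees itself as 1/25 of its 5x5 window
        assert stack[R.SUAEDA][3, 3] == pytest.approx(1 / 25)

    def test_static_cells_score_zero(self, grid_factory):
        v = np.full((5, 5), R.SUAEDA)
        v[2, 2] = R.WATER
        g = grid_factory(v)
        stack = neighborhood_suitability(g, IDENTITY, SimulationConfig())
        assert stack[R.SUAEDA][2, 2] == 0.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_scan(self, random_grid, seed):
        g = random_grid(12, 11, seed=seed)
        cfg = SimulationConfig(filter_size=5)
        stack = neighborhood_suitability(g, PUBLISHED, cfg)
        for code in DYN:
            np.testing.assert_allclose(
                stack[code], brute_force_suitability(g, PUBLISHED, code, 5),
                atol=1e-12)


class TestLargestRemainder:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_apportionment(self, seed):
        rng = np.random.default_rng(seed)
        fracs = rng.uniform(0.1, 5.0, size=rng.integers(2, 7))
        total = int(rng.integers(10, 5000))
        got = largest_remainder_round(fracs, total)
        assert got.sum() == total
        np.testing.assert_array_equal(got, naive_largest_remainder(fracs, total))


class TestStep:
    def test_identity_matrix_is_fixed_point(self, random_grid):
        g = random_grid(20, 20, seed=5)
        out = step(g, IDENTITY, SimulationConfig(seed=1))
        np.testing.assert_array_equal(out.values, g.values)
        assert out.date == g.date + 1

    def test_absorbing_matrix_converts_strip(self, grid_factory):
        # everything flows to mudflat in one step
        absorbing = TransitionMatrix(
            np.array([[0, 0, 1.0], [0, 0, 1.0], [0, 0, 1.0]]), DYN)
        g = grid_factory(np.array([[R.SUAEDA] * 10]))
        out = step(g, absorbing, SimulationConfig(seed=0))
        assert (out.values == R.MUDFLAT).all()

    def test_statics_and_nodata_pass_through(self, grid_factory, scheme):
        v = np.full((10, 10), R.SUAEDA)
        v[0, :] = R.WATER
        v[1, :] = scheme.nodata_code
        out = step(grid_factory(v), PUBLISHED, SimulationConfig(seed=2))
        assert (out.values[0, :] == R.WATER).all()
        assert (out.values[1, :] == scheme.nodata_code).all()

    def test_counts_equal_independent_demands(self, grid_factory):
        g = make_banded_grid(SyntheticConfig(rows=80, cols=80, seed=3), date=1990)
        out = step(g, PUBLISHED, SimulationConfig(seed=9))
        counts = np.array([(g.values == c).sum() for c in DYN], dtype=float)
        sel = [PUBLISHED.class_codes.index(c) for c in DYN]
        expected = counts @ PUBLISHED.probs[np.ix_(sel, sel)]
        demand = naive_largest_remainder(expected, int(counts.sum()))
        for c, d in zip(DYN, demand):
            assert (out.values == c).sum() == d


class TestRun:
    def test_one_year_equals_one_step(self, random_grid):
        g = random_grid(15, 15, seed=8)
        cfg = SimulationConfig(seed=21)
        np.testing.assert_array_equal(
            run(g, PUBLISHED, cfg, 1)[0].values,
            step(g, PUBLISHED, cfg, rng=np.random.default_rng(21)).values)

    def test_same_seed_reproduces_exactly(self, random_grid):
        g = random_grid(25, 25, seed=2)
        cfg = SimulationConfig(seed=77)
        a = run(g, PUBLISHED, cfg, 4)
        b = run(g, PUBLISHED, cfg, 4)
        for ga, gb in zip(a, b):
            np.testing.assert_array_equal(ga.values, gb.values)

    def test_identity_fixed_point_over_years(self, random_grid):
        g = random_grid(15, 15, seed=6)
        for out in run(g, IDENTITY, SimulationConfig(seed=3), 5):
            np.testing.assert_array_equal(out.values, g.values)

    def test_dynamic_cell_total_conserved(self):
        g = make_banded_grid(SyntheticConfig(rows=60, cols=60, seed=4), date=1990)
        n0 = np.isin(g.values, DYN).sum()
        for out in run(g, PUBLISHED, SimulationConfig(seed=11), 6):
            assert np.isin(out.values, DYN).sum() == n0

    def test_allocator_is_spatially_coherent(self):
        """Output is more spatially clumped than a random relabelling with
        the same class counts (the contagion property of the allocator)."""
        from marshca.ca import _window_counts

        g = make_banded_grid(SyntheticConfig(rows=60, cols=60, seed=5), date=1990)
        out = run(g, PUBLISHED, SimulationConfig(seed=13), 5)[-1]

        def mean_within_class_fraction(values):
            dyn = np.isin(values, DYN)
            den = np.where(_window_counts(dyn, 5) > 0, _window_counts(dyn, 5), 1)
            acc = 0.0
            for c in DYN:
                frac = _window_counts(dyn & (values == c), 5) / den
                acc += frac[dyn & (values == c)].sum()
            return acc / dyn.sum()

        rng = np.random.default_rng(0)
        shuffled = out.values.copy()
        dyn_idx = np.flatnonzero(np.isin(shuffled.ravel(), DYN))
        vals = shuffled.ravel()[dyn_idx]
        shuffled.ravel()[dyn_idx] = rng.permutation(vals)
        assert mean_within_class_fraction(out.values) >= \
            mean_within_class_fraction(shuffled)

    def test_areas_track_markov_projection(self):
        """Class areas from the spatial run match the pure Markov projection
        up to per-step rounding (<= K cells per step)."""
        from marshca import class_areas, project_areas

        g = make_banded_grid(SyntheticConfig(rows=80, cols=80, seed=6), date=1990)
        n_years = 5
        out = run(g, PUBLISHED, SimulationConfig(seed=17), n_years)[-1]
        areas0 = {c: float((g.values == c).sum()) for c in DYN}
        projected = project_areas(areas0, PUBLISHED, n_years)
        tol_cells = 3 * n_years
        for c in DYN:
            assert abs((out.values == c).sum() - projected[c]) <= tol_cells
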