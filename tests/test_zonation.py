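"""Baseline-referenced zonation geometry: L = S/D, centroids, movements."""

import numpy as np
import pytest

from marshca import area_series, boundary_profile, movement, percent_change
from marshca import reference as R
from marshca.zonation import ClassAbsentError, ZonationProfile


def make_profile(code, date, centroid, near=None, far=None):
    near = centroid if near is None else near
    far = centroid if far is None else far
    return ZonationProfile(
        class_code=code, date=date,
        mean_distance_nearest=near, mean_distance_farthest=far,
        centroid_distance=centroid, projected_length=1.0,
        enclosed_area_nearest=near, enclosed_area_farthest=far)


def brute_force_profile(grid, code):
    """Independent per-transect scan in the canonical baseline-on-top frame."""
    v = grid.oriented()
    cs = grid.cell_size
    nears, fars, all_d = [], [], []
    for j in range(v.shape[1]):
        rows = [r for r in range(v.shape[0]) if v[r, j] == code]
        if not rows:
            continue
        nears.append((min(rows) + 0.5) * cs)
        fars.append((max(rows) + 0.5) * cs)
        all_d += [(r + 0.5) * cs for r in rows]
    D = len(nears) * cs
    return (sum(nears) * cs / D, sum(fars) * cs / D,
            sum(all_d) / len(all_d), D)


class TestBoundaryProfile:
    def test_straight_band_closed_form(self, grid_factory):
        # band occupying rows 10..19 of a 30x12 grid, baseline on top
        v = np.full((30, 12), R.MUDFLAT)
        v[10:20, :] = R.SUAEDA
        p = boundary_profile(grid_factory(v), R.SUAEDA)
        assert p.mean_distance_nearest == pytest.approx((10 + 0.5) * 30)
        assert p.mean_distance_farthest == pytest.approx((19 + 0.5) * 30)
        assert p.band_width == pytest.approx(270.0)
        assert p.centroid_distance == pytest.approx(
            (p.mean_distance_nearest + p.mean_distance_farthest) / 2)
        assert p.projected_length == 12 * 30

    def test_staircase_boundary_hand_sum(self, grid_factory):
        # nearest row indices per column: 2,2,3,3,4,4,5,5,6,6
        v = np.full((12, 10), R.MUDFLAT)
        for j in range(10):
            v[2 + j // 2:, j] = R.SUAEDA
        p = boundary_profile(grid_factory(v), R.SUAEDA)
        hand = sum((2 + j // 2 + 0.5) * 30 for j in range(10)) * 30 / (10 * 30)
        assert p.mean_distance_nearest == pytest.approx(hand)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_ragged_grids(self, random_grid, seed):
        g = random_grid(25, 18, seed=seed)
        for code in (R.PHRAGMITES, R.SUAEDA, R.MUDFLAT):
            p = boundary_profile(g, code)
            near, far, cent, D = brute_force_profile(g, code)
            assert p.mean_distance_nearest == pytest.approx(near, abs=1e-9)
            assert p.mean_distance_farthest == pytest.approx(far, abs=1e-9)
            assert p.centroid_distance == pytest.approx(cent, abs=1e-9)
            assert p.projected_length == pytest.approx(D)

    def test_seaward_translation_shifts_all_metrics(self, grid_factory):
        v = np.full((40, 10), R.MUDFLAT)
        v[5:12, :] = R.SUAEDA
        shifted = np.full((40, 10), R.MUDFLAT)
        shifted[12:19, :] = R.SUAEDA
        a = boundary_profile(grid_factory(v), R.SUAEDA)
        b = boundary_profile(grid_factory(shifted), R.SUAEDA)
        assert b.mean_distance_nearest - a.mean_distance_nearest == pytest.approx(7 * 30)
        assert b.mean_distance_farthest - a.mean_distance_farthest == pytest.approx(7 * 30)
        assert b.centroid_distance - a.centroid_distance == pytest.approx(7 * 30)
        assert b.band_width == pytest.approx(a.band_width)

    @pytest.mark.parametrize("edge", ["north", "south", "west", "east"])
    def test_profile_independent_of_baseline_orientation(self, grid_factory, edge):
        canonical = np.full((20, 8), R.MUDFLAT)
        canonical[4:9, :] = R.SUAEDA
        transforms = {
            "north": lambda v: v,
            "south": lambda v: v[::-1, :],
            "west": lambda v: v.T,
            "east": lambda v: v[::-1, :].T,
        }
        g = grid_factory(transforms[edge](canonical).copy(), baseline_edge=edge)
        p = boundary_profile(g, R.SUAEDA)
        assert p.mean_distance_nearest == pytest.approx(4.5 * 30)
        assert p.mean_distance_farthest == pytest.approx(8.5 * 30)

    def test_absent_class_raises_not_nan(self, grid_factory):
        g = grid_factory(np.full((5, 5), R.MUDFLAT))
        with pytest.raises(ClassAbsentError, match="absent"):
            boundary_profile(g, R.SPARTINA)

    def test_min_patch_filter_drops_specks(self, grid_factory):
        v = np.full((30, 10), R.MUDFLAT)
        v[20:25, :] = R.SUAEDA
        v[2, 3] = R.SUAEDA  # isolated landward speck
        g = grid_factory(v)
        unfiltered = boundary_profile(g, R.SUAEDA)
        filtered = boundary_profile(g, R.SUAEDA, min_patch_cells=4)
        assert unfiltered.mean_distance_nearest < filtered.mean_distance_nearest
        assert filtered.mean_distance_nearest == pytest.approx(20.5 * 30)


class TestMovement:
    def test_published_phragmites_centroid_shift(self):
        """Centroid 5079.82 m (1995) -> 5957.32 m (2017): 877.50 m at 39.89 m/yr."""
        a = make_profile(R.PHRAGMITES, 1995, R.CENTROID_DISTANCE_M[R.PHRAGMITES][1995])
        b = make_profile(R.PHRAGMITES, 2017, R.CENTROID_DISTANCE_M[R.PHRAGMITES][2017])
        rec = {m.which: m for m in movement(a, b)}["centroid"]
        assert rec.displacement == pytest.approx(877.50)
        assert rec.rate == pytest.approx(39.89, abs=0.005)
        assert rec.rate * (2017 - 1995) == pytest.approx(rec.displacement)

    def test_published_suaeda_centroid_shift(self):
        a = make_profile(R.SUAEDA, 1995, R.CENTROID_DISTANCE_M[R.SUAEDA][1995])
        b = make_profile(R.SUAEDA, 2017, R.CENTROID_DISTANCE_M[R.SUAEDA][2017])
        rec = {m.which: m for m in movement(a, b)}["centroid"]
        assert rec.displacement == pytest.approx(1281.10)
        assert rec.rate == pytest.approx(58.23, abs=0.005)

    def test_identical_profiles_zero_movement(self):
        a = make_profile(R.SUAEDA, 1995, 5000.0)
        b = make_profile(R.SUAEDA, 2000, 5000.0)
        assert all(m.displacement == 0 and m.rate == 0 for m in movement(a, b))

    def test_antisymmetry_in_displacement(self, grid_factory):
        v1 = np.full((30, 10), R.MUDFLAT)
        v1[5:10, :] = R.SUAEDA
        v2 = np.full((30, 10), R.MUDFLAT)
        v2[8:15, :] = R.SUAEDA
        pa = boundary_profile(grid_factory(v1, date=1995), R.SUAEDA)
        pb = boundary_profile(grid_factory(v2, date=2000), R.SUAEDA)
        fwd = {m.which: m.displacement for m in movement(pa, pb)}
        pa2 = make_profile(R.SUAEDA, 1995, pb.centroid_distance,
                           pb.mean_distance_nearest, pb.mean_distance_farthest)
        pb2 = make_profile(R.SUAEDA, 2000, pa.centroid_distance,
                           pa.mean_distance_nearest, pa.mean_distance_farthest)
        rev = {m.which: m.displacement for m in movement(pa2, pb2)}
        for key in fwd:
            assert fwd[key] == pytest.approx(-rev[key])

    def test_date_order_enforced(self):
        a = make_profile(R.SUAEDA, 2000, 100.0)
        b = make_profile(R.SUAEDA, 1995, 200.0)
        with pytest.raises(ValueError, match="date"):
            movement(a, b)


class TestAreaSeries:
    def test_published_percent_changes(self):
        """Worked percent/ratio arithmetic on the published area record."""
        assert percent_change(R.SPARTINA_1985_NARRATIVE_HA,
                              R.AREAS_HA[R.SPARTINA][2017]) == pytest.approx(662.92, abs=0.01)
        ratio = R.AREAS_HA[R.PHRAGMITES][2017] / R.AREAS_HA[R.PHRAGMITES][1985]
        assert ratio == pytest.approx(1.74, abs=0.005)
        reduction = -percent_change(R.SUAEDA_2017_SIMULATED_HA,
                                    R.AREAS_HA[R.SUAEDA][2017])
        assert reduction == pytest.approx(82.47, abs=0.005)

    def test_published_proportions(self):
        assert R.AREAS_HA[R.SUAEDA][1985] / R.TOTAL_AREA_HA[1985] * 100 == \
            pytest.approx(15.83, abs=0.005)
        assert R.AREAS_HA[R.PHRAGMITES][2017] / R.TOTAL_AREA_HA[2017] * 100 == \
            pytest.approx(36.72, abs=0.005)
        assert R.AREAS_HA[R.MUDFLAT][2017] / R.TOTAL_AREA_HA[2017] * 100 == \
            pytest.approx(34.81, abs=0.005)

    def test_single_class_is_100_percent(self, grid_factory):
        g = grid_factory(np.full((5, 5), R.MUDFLAT))
        df = area_series([g])
        row = df[(df.class_code == R.MUDFLAT)].iloc[0]
        assert row.proportion_pct == pytest.approx(100.0)

    def test_proportions_sum_to_100_per_date(self, random_grid):
        grids = [random_grid(seed=s, date=1985 + 5 * s) for s in range(3)]
        df = area_series(grids)
        for _, sub in df.groupby("date"):
            assert sub.proportion_pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_changes_relative_to_earlier_date(self, grid_factory):
        a = np.full((10, 10), R.MUDFLAT)
        b = a.copy()
        b[:5, :] = R.SUAEDA  # mudflat halves: 9.0 -> 4.5 ha
        df = area_series([grid_factory(a, date=1985), grid_factory(b, date=1990)])
        row = df[(df.date == 1990) & (df.class_code == R.MUDFLAT)].iloc[0]
        assert row.percent_change == pytest.approx(-50.0)
        assert row.ratio == pytest.approx(0.5)
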