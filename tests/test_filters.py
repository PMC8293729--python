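"""Masking, ranking, area & elevation filters, manual adjustment, KS engine."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oakmap.ensemble import ProbabilityRaster
from oakmap.filters import (
    ElevationHistogram,
    MaskedRaster,
    RankedPixels,
    area_filter,
    compare_selections_ks,
    elevation_filter,
    manual_adjust_check,
    mask_to_broadleaf,
    rank_pixels,
)
from oakmap.grids import GridSpec
from oakmap.synthetic import ALL_SPECIES, StandPolygonLayer


def prob_raster(values, grid=None, region=0):
    values = np.asarray(values, dtype=float)
    grid = grid or GridSpec(*values.shape, region_count=1)
    return ProbabilityRaster(region_id=region, values=values, grid=grid, provenance={})


def stand_layer(grid, labels, ifts):
    table = pd.DataFrame(
        {
            "region_id": 0,
            "ift": ifts,
            "n_pixels": [int((labels == i).sum()) for i in range(len(ifts))],
            "area_ha": 0.0,
            "ownership": "private",
            "occupied": False,
        },
        index=pd.Index(range(len(ifts)), name="stand_id"),
    )
    for sp in ALL_SPECIES:
        table[f"pct_{sp}"] = 0
    return StandPolygonLayer(grid=grid, labels=np.asarray(labels, np.int32), table=table)


def ranked_from(values, eligible=None, grid=None):
    values = np.asarray(values, dtype=float)
    grid = grid or GridSpec(*values.shape, region_count=1)
    eligible = np.ones(values.shape, bool) if eligible is None else eligible
    return rank_pixels(MaskedRaster(values=values, eligible=eligible, grid=grid))


class TestMasking:
    def test_polygon_covering_whole_grid_changes_nothing(self):
        grid = GridSpec(4, 4, region_count=1)
        prob = prob_raster(np.full((4, 4), 0.7), grid)
        stands = stand_layer(grid, np.zeros((4, 4), int), ["broadleaved"])
        masked = mask_to_broadleaf(prob, stands)
        assert masked.eligible.all()
        np.testing.assert_array_equal(masked.values, prob.values)

    def test_no_qualifying_polygons_zeroes_everything(self):
        grid = GridSpec(4, 4, region_count=1)
        prob = prob_raster(np.full((4, 4), 0.7), grid)
        stands = stand_layer(grid, np.zeros((4, 4), int), ["conifer"])
        masked = mask_to_broadleaf(prob, stands)
        assert not masked.eligible.any()
        assert (masked.values == 0).all()

    def test_half_grid_containment_recount(self):
        # left half broadleaved -> exactly 8 eligible pixels
        grid = GridSpec(4, 4, region_count=1)
        labels = np.zeros((4, 4), int)
        labels[:, 2:] = 1
        prob = prob_raster(np.full((4, 4), 0.5), grid)
        stands = stand_layer(grid, labels, ["broadleaved", "conifer"])
        masked = mask_to_broadleaf(prob, stands)
        assert masked.eligible.sum() == 8
        assert masked.eligible[:, :2].all()

    def test_grid_mismatch_rejected(self):
        prob = prob_raster(np.full((4, 4), 0.5))
        stands = stand_layer(GridSpec(4, 5, region_count=1), np.zeros((4, 5), int), ["broadleaved"])
        with pytest.raises(ValueError):
            mask_to_broadleaf(prob, stands)

    def test_nodata_pixels_ineligible(self):
        grid = GridSpec(2, 2, region_count=1)
        values = np.array([[0.5, np.nan], [0.5, 0.5]])
        stands = stand_layer(grid, np.zeros((2, 2), int), ["broadleaved"])
        masked = mask_to_broadleaf(prob_raster(values, grid), stands)
        assert not masked.eligible[0, 1]
        assert masked.values[0, 1] == 0


class TestRanking:
    def test_descending_rowmajor_is_identity(self):
        values = np.array([[0.9, 0.8], [0.7, 0.6]])
        ranked = ranked_from(values)
        np.testing.assert_array_equal(ranked.probs, [0.9, 0.8, 0.7, 0.6])
        np.testing.assert_array_equal(ranked.rows, [0, 0, 1, 1])

    def test_all_equal_values_fall_back_to_rowmajor(self):
        ranked = ranked_from(np.full((3, 3), 0.5))
        np.testing.assert_array_equal(ranked.rows, np.repeat(np.arange(3), 3))
        np.testing.assert_array_equal(ranked.cols, np.tile(np.arange(3), 3))

    def test_random_raster_matches_stable_sort_oracle(self, rng):
        values = rng.random((6, 7))
        ranked = ranked_from(values)
        # independent oracle: python sorted() on (-p, row, col)
        cells = [(-values[r, c], r, c) for r in range(6) for c in range(7)]
        expect = sorted(cells)
        np.testing.assert_array_equal(ranked.rows, [r for _, r, _ in expect])
        np.testing.assert_array_equal(ranked.cols, [c for _, _, c in expect])

    def test_empty_eligible_set_rejected(self):
        with pytest.raises(ValueError, match="eligible"):
            ranked_from(np.full((2, 2), 0.5), eligible=np.zeros((2, 2), bool))


class TestAreaFilter:
    def test_zero_target_selects_nothing(self, rng):
        ranked = ranked_from(rng.random((3, 3)))
        sel = area_filter(ranked, 0.0)
        assert sel.n_selected == 0
        assert np.isnan(sel.min_selected_probability)

    def test_up_to_semantics_arithmetic(self, rng):
        # 10 pixels at 0.25 ha, target 1.1 ha -> max{k: 0.25k <= 1.1} = 4
        ranked = ranked_from(rng.random((2, 5)))
        sel = area_filter(ranked, 1.1)
        assert sel.n_selected == 4
        assert sel.achieved_area == pytest.approx(1.0)

    def test_pool_exhaustion_records_shortfall(self, rng):
        ranked = ranked_from(rng.random((2, 2)))
        sel = area_filter(ranked, 10.0)
        assert sel.n_selected == 4
        assert sel.shortfall_area == pytest.approx(10.0 - 4 * 0.25)

    def test_selects_exactly_the_top_ranked(self, rng):
        values = rng.random((4, 4))
        ranked = ranked_from(values)
        sel = area_filter(ranked, 1.5)  # 6 pixels
        assert set(sel.probs) == set(np.sort(values.ravel())[-6:])

    def test_negative_target_rejected(self, rng):
        with pytest.raises(ValueError):
            area_filter(ranked_from(rng.random((2, 2))), -1.0)

    @given(target=st.floats(0, 5), seed=st.integers(0, 50))
    @settings(derandomize=True, max_examples=40)
    def test_optimality_and_monotonicity(self, target, seed):
        values = np.random.default_rng(seed).random((4, 5))
        ranked = ranked_from(values)
        sel = area_filter(ranked, target)
        if 0 < sel.n_selected < len(ranked):
            unselected_max = ranked.probs[sel.n_selected :].max()
            assert unselected_max <= sel.min_selected_probability + 1e-12
        bigger = area_filter(ranked, target + 0.5)
        assert set(zip(sel.rows, sel.cols)) <= set(zip(bigger.rows, bigger.cols))


def brute_force_elevation_selection(probs, classes, quota):
    """Enumerate all quota-respecting subsets; return the max-probability one."""
    idx = range(len(probs))
    best, best_sum = None, -1.0
    for r in range(len(probs) + 1):
        for subset in itertools.combinations(idx, r):
            counts = {}
            for i in subset:
                counts[classes[i]] = counts.get(classes[i], 0) + 1
            if any(c > quota.get(k, 0) for k, c in counts.items()):
                continue
            # must be maximal: no class left under quota with pixels spare
            maximal = all(
                counts.get(k, 0) >= min(quota.get(k, 0), sum(1 for i in idx if classes[i] == k))
                for k in set(classes)
            )
            if not maximal:
                continue
            s = sum(probs[i] for i in subset)
            if s > best_sum:
                best, best_sum = set(subset), s
    return best


class TestElevationFilter:
    def grid_with_dem(self, probs, elevs):
        n = len(probs)
        grid = GridSpec(1, n, region_count=1)
        values = np.asarray(probs, float).reshape(1, n)
        dem = np.asarray(elevs, float).reshape(1, n)
        return ranked_from(values, grid=grid), dem

    def test_two_class_toy_matches_brute_force(self):
        # class A (elev 5): probs .9/.8/.3, quota 2; class B (elev 15): .7/.1, quota 1
        probs = [0.9, 0.8, 0.3, 0.7, 0.1]
        elevs = [5, 5, 5, 15, 15]
        ranked, dem = self.grid_with_dem(probs, elevs)
        quota = ElevationHistogram({0.0: 2, 10.0: 1})
        sel = elevation_filter(ranked, dem, quota)
        assert sorted(sel.probs, reverse=True) == [0.9, 0.8, 0.7]
        oracle = brute_force_elevation_selection(
            probs, [0.0, 0.0, 0.0, 10.0, 10.0], {0.0: 2, 10.0: 1}
        )
        got = {list(zip(ranked.rows, ranked.cols)).index((r, c)) for r, c in zip(sel.rows, sel.cols)}
        assert {round(probs[i], 6) for i in oracle} == set(np.round(sel.probs, 6))

    def test_random_toys_match_brute_force(self, rng):
        for _ in range(5):
            n = 12
            probs = np.round(rng.random(n), 6).tolist()
            elevs = rng.choice([5.0, 15.0, 25.0], size=n).tolist()
            quota_counts = {0.0: int(rng.integers(0, 4)), 10.0: int(rng.integers(0, 4)), 20.0: int(rng.integers(0, 4))}
            ranked, dem = self.grid_with_dem(probs, elevs)
            sel = elevation_filter(ranked, dem, ElevationHistogram(quota_counts))
            classes = [float(np.floor(e / 10) * 10) for e in elevs]
            oracle = brute_force_elevation_selection(probs, classes, quota_counts)
            assert {round(probs[i], 6) for i in oracle} == set(np.round(sel.probs, 6))

    def test_quota_equal_to_availability_selects_everything(self, rng):
        probs = rng.random(8).tolist()
        elevs = [5] * 4 + [15] * 4
        ranked, dem = self.grid_with_dem(probs, elevs)
        sel = elevation_filter(ranked, dem, ElevationHistogram({0.0: 4, 10.0: 4}))
        assert sel.n_selected == 8
        assert not sel.shortfalls

    def test_empty_class_shortfall_recorded_not_reallocated(self, rng):
        probs = rng.random(4).tolist()
        elevs = [5, 5, 5, 5]
        ranked, dem = self.grid_with_dem(probs, elevs)
        sel = elevation_filter(ranked, dem, ElevationHistogram({0.0: 2, 50.0: 5}))
        assert sel.n_selected == 2  # deficit NOT filled from class 0
        assert sel.shortfalls == {50.0: 5}

    def test_mass_conservation(self, rng):
        probs = rng.random(20).tolist()
        elevs = rng.choice([5, 15, 25, 35], size=20).tolist()
        ranked, dem = self.grid_with_dem(probs, elevs)
        quota = ElevationHistogram({0.0: 3, 10.0: 2, 20.0: 4, 30.0: 1})
        sel = elevation_filter(ranked, dem, quota)
        assert sel.n_selected == sum(sel.per_class_achieved.counts.values())
        for lo, got in sel.per_class_achieved.counts.items():
            assert got <= quota.counts[lo]

    def test_quota_monotonicity(self, rng):
        probs = rng.random(15).tolist()
        elevs = rng.choice([5, 15], size=15).tolist()
        ranked, dem = self.grid_with_dem(probs, elevs)
        small = elevation_filter(ranked, dem, ElevationHistogram({0.0: 2, 10.0: 2}))
        big = elevation_filter(ranked, dem, ElevationHistogram({0.0: 4, 10.0: 3}))
        assert set(zip(small.rows, small.cols)) <= set(zip(big.rows, big.cols))

    def test_negative_quota_rejected(self):
        with pytest.raises(ValueError):
            ElevationHistogram({0.0: -1})


class TestElevationHistogram:
    def test_half_open_binning_convention(self):
        h = ElevationHistogram.from_values([0, 9.99, 10, 19.5, 20])
        assert h.counts == {0.0: 2, 10.0: 2, 20.0: 1}

    def test_misaligned_lower_bound_rejected(self):
        with pytest.raises(ValueError):
            ElevationHistogram({5.0: 1})

    def test_scaled_to_total_preserves_shape_and_sum(self):
        h = ElevationHistogram({0.0: 3, 10.0: 6, 20.0: 1})
        s = h.scaled_to_total(100)
        assert s.total() == 100
        assert s.counts[10.0] == 60

    @given(n=st.integers(0, 500))
    @settings(derandomize=True, max_examples=30)
    def test_scaling_always_hits_target_total(self, n):
        h = ElevationHistogram({0.0: 2, 10.0: 5, 20.0: 3, 40.0: 7})
        assert h.scaled_to_total(n).total() == n


class TestManualAdjust:
    def test_empty_training_set_is_noop(self):
        prob = prob_raster(np.full((3, 3), 0.4))
        adjusted, diff = manual_adjust_check(prob, (np.array([], int), np.array([], int)))
        assert diff == 0.0
        np.testing.assert_array_equal(adjusted, prob.values)

    def test_already_certain_pixels_give_zero_difference(self):
        prob = prob_raster(np.ones((2, 2)))
        adjusted, diff = manual_adjust_check(prob, (np.array([0, 1]), np.array([0, 1])))
        assert diff == 0.0

    def test_hand_computed_mean_difference(self):
        values = np.array([[0.99, 0.98], [1.00, 0.5]])
        prob = prob_raster(values)
        rows, cols = np.array([0, 0, 1]), np.array([0, 1, 0])
        adjusted, diff = manual_adjust_check(prob, (rows, cols))
        assert diff == pytest.approx((0.01 + 0.02 + 0.0) / 3)
        assert (adjusted[rows, cols] == 1.0).all()
        assert adjusted[1, 1] == 0.5  # untouched elsewhere

    def test_off_grid_training_pixel_rejected(self):
        prob = prob_raster(np.full((2, 2), 0.5))
        with pytest.raises(ValueError, match="outside"):
            manual_adjust_check(prob, (np.array([5]), np.array([0])))


def ecdf_oracle_D(a, b):
    """sup |ECDF_a - ECDF_b| evaluated at every sample point."""
    pts = sorted(set(a) | set(b))
    return max(
        abs(sum(x <= t for x in a) / len(a) - sum(x <= t for x in b) / len(b))
        for t in pts
    )


class TestKs:
    def test_identical_samples_have_zero_D(self, rng):
        x = rng.random(50)
        D, p = compare_selections_ks(x, x.copy())
        assert D == 0.0

    def test_disjoint_supports_have_D_one(self):
        D, _ = compare_selections_ks([1, 2, 3], [10, 11, 12])
        assert D == 1.0

    def test_small_sample_matches_ecdf_enumeration(self):
        a, b = [1, 2, 3], [2, 3, 4]
        D, _ = compare_selections_ks(a, b)
        assert D == pytest.approx(1 / 3)
        assert D == pytest.approx(ecdf_oracle_D(a, b))

    def test_random_samples_match_ecdf_enumeration(self, rng):
        a = rng.random(20)
        b = rng.random(30) ** 2
        D, _ = compare_selections_ks(a, b)
        assert D == pytest.approx(ecdf_oracle_D(list(a), list(b)))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_selections_ks([], [1.0])
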