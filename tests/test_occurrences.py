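"""Cleaning, thinning, aggregation, coastal buffers, and background sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ensdm import (
    aggregate_to_grid,
    build_training_table,
    clean_occurrences,
    coastal_buffer_mask,
    make_grid,
    sample_pseudo_absences,
    thin_occurrences,
)
from ensdm.grids import GridSpec, PredictorStack, Raster, haversine_km


def occ_table(rows):
    return pd.DataFrame(rows, columns=["species", "lon", "lat", "year"])


EXTENT = (110.0, 120.0, 20.0, 30.0)


class TestClean:
    def test_duplicates_collapsed(self):
        raw = occ_table([("a", 111.0, 21.0, 2020), ("a", 111.0, 21.0, 2020)])
        out, rep = clean_occurrences(raw, EXTENT)
        assert len(out) == 1 and rep.n_duplicates == 1

    def test_old_record_dropped(self):
        raw = occ_table([("a", 111.0, 21.0, 2010), ("a", 112.0, 21.0, 2020)])
        out, rep = clean_occurrences(raw, EXTENT, year_range=(2014, 2024))
        assert len(out) == 1 and rep.n_outside_years == 1

    def test_out_of_extent_counted(self):
        raw = occ_table([("a", 150.0, 21.0, 2020), ("a", 112.0, 21.0, 2020)])
        out, rep = clean_occurrences(raw, EXTENT)
        assert len(out) == 1 and rep.n_outside_extent == 1

    def test_off_land_dropped(self):
        grid = make_grid(EXTENT, 1.0)
        land = np.ones(grid.shape)
        land[:, -1] = 0.0  # eastern column is sea
        raw = occ_table([("a", 119.5, 21.5, 2020), ("a", 112.5, 21.5, 2020)])
        out, rep = clean_occurrences(raw, EXTENT, land=Raster(grid, land))
        assert len(out) == 1 and rep.n_off_land == 1

    def test_empty_result_warns_not_fails(self):
        raw = occ_table([("a", 111.0, 21.0, 1999)])
        with pytest.warns(UserWarning, match="no occurrence"):
            out, _ = clean_occurrences(raw, EXTENT)
        assert out.empty

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            clean_occurrences(occ_table([]), EXTENT)


class TestThin:
    def test_close_pair_collapses(self):
        # ~100 m apart: same 1-km cell
        raw = occ_table([("a", 111.0005, 21.0005, 2020), ("a", 111.0009, 21.0009, 2021)])
        assert len(thin_occurrences(raw)) == 1

    def test_distant_pair_survives(self):
        raw = occ_table([("a", 111.0, 21.0, 2020), ("a", 111.05, 21.0, 2020)])  # ~5 km
        assert len(thin_occurrences(raw)) == 2

    def test_tiebreak_keeps_earliest_year(self):
        raw = occ_table([("a", 111.0005, 21.0005, 2022), ("a", 111.0006, 21.0005, 2016)])
        out = thin_occurrences(raw)
        assert out.iloc[0]["year"] == 2016

    def test_species_thinned_independently(self):
        raw = occ_table([("a", 111.0005, 21.0005, 2020), ("b", 111.0006, 21.0006, 2020)])
        assert len(thin_occurrences(raw)) == 2

    @given(
        n=st.integers(1, 40),
        seed=st.integers(0, 10),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_thinning_is_idempotent(self, n, seed):
        rng = np.random.default_rng(seed)
        raw = occ_table(
            [("a", 110 + rng.uniform(0, 0.2), 20 + rng.uniform(0, 0.2), int(rng.integers(2014, 2025)))
             for _ in range(n)]
        )
        once = thin_occurrences(raw)
        twice = thin_occurrences(once)
        pd.testing.assert_frame_equal(once, twice)


class TestAggregate:
    def test_multiple_points_one_cell(self):
        grid = make_grid(EXTENT, 0.1)
        raw = occ_table([("a", 111.01, 21.01, 2020), ("a", 111.02, 21.02, 2020), ("a", 111.09, 21.09, 2020)])
        assert aggregate_to_grid(raw, grid).size == 1

    def test_k_distinct_cells(self):
        grid = make_grid(EXTENT, 0.1)
        raw = occ_table([("a", 111.05 + 0.1 * k, 21.05, 2020) for k in range(5)])
        assert aggregate_to_grid(raw, grid).size == 5

    def test_edge_point_follows_half_open_rule(self):
        grid = make_grid((0, 1, 0, 1), 0.5)
        raw = occ_table([("a", 0.5, 0.5, 2020)])
        cell = aggregate_to_grid(raw, grid)
        assert cell.tolist() == [1 * grid.n_cols + 1]

    def test_masked_cell_dropped_with_warning(self):
        grid = make_grid(EXTENT, 0.1)
        valid = np.ones(grid.shape, dtype=bool)
        valid[grid.cell_of([111.05], [21.05])] = False
        raw = occ_table([("a", 111.05, 21.05, 2020)])
        with pytest.warns(UserWarning, match="masked"):
            cells = aggregate_to_grid(raw, grid, valid)
        assert cells.size == 0


class TestCoastalBuffer:
    @pytest.fixture(scope="class")
    def coast_setup(self):
        grid = make_grid((110, 114, 20, 24), 0.1)  # 40x40
        coast_vals = np.zeros(grid.shape)
        coast_vals[:, -1] = 2.0  # coast along the eastern column
        return grid, Raster(grid, coast_vals)

    def test_coast_cell_included_at_distance_zero(self, coast_setup):
        grid, coast = coast_setup
        mask = coastal_buffer_mask(grid, coast, 200.0)
        assert (mask.values[:, -1] > 0).all()

    def test_matches_brute_force_haversine(self, coast_setup):
        grid, coast = coast_setup
        mask = coastal_buffer_mask(grid, coast, 150.0)
        lon = grid.lon_centers()
        lat = grid.lat_centers()
        ci, cj = np.nonzero(coast.values == 2.0)
        for i in range(grid.n_rows):
            for j in range(grid.n_cols):
                d = haversine_km(
                    np.full(ci.size, lon[j]), np.full(ci.size, lat[i]), lon[cj], lat[ci]
                ).min()
                assert (mask.values[i, j] > 0) == (d <= 150.0)

    def test_buffer_monotone_in_distance(self, coast_setup):
        grid, coast = coast_setup
        near = coastal_buffer_mask(grid, coast, 100.0).values > 0
        far = coastal_buffer_mask(grid, coast, 200.0).values > 0
        assert (near <= far).all()

    def test_empty_coast_rejected(self, coast_setup):
        grid, _ = coast_setup
        with pytest.raises(ValueError):
            coastal_buffer_mask(grid, Raster(grid, np.zeros(grid.shape)), 200.0)


class TestPseudoAbsences:
    @pytest.fixture(scope="class")
    def domain(self):
        grid = make_grid((110, 115, 20, 25), 0.1)  # 50x50 = 2500 cells
        valid = np.ones(grid.shape, dtype=bool)
        return grid, valid

    @pytest.mark.parametrize("n_pres,expected", [(254, 508), (90, 180)])
    def test_two_to_one_ratio(self, domain, n_pres, expected):
        grid, valid = domain
        presences = np.arange(n_pres)
        absences = sample_pseudo_absences(valid, presences, grid, ratio=2, seed=0)
        assert absences.size == expected

    def test_presence_cells_excluded(self, domain):
        grid, valid = domain
        presences = np.arange(100)
        absences = sample_pseudo_absences(valid, presences, grid, seed=1)
        assert np.intersect1d(presences, absences).size == 0

    def test_reproducible_per_seed(self, domain):
        grid, valid = domain
        a = sample_pseudo_absences(valid, np.arange(50), grid, seed=9)
        b = sample_pseudo_absences(valid, np.arange(50), grid, seed=9)
        assert np.array_equal(a, b)

    def test_coastal_buffer_constrains_samples(self, domain):
        grid, valid = domain
        buf = np.zeros(grid.shape)
        buf[:, :10] = 1.0
        absences = sample_pseudo_absences(
            valid, np.arange(20), grid, background="coastal-buffer",
            buffer_mask=Raster(grid, buf), seed=2,
        )
        cols = absences % grid.n_cols
        assert (cols < 10).all()

    def test_shortfall_named_in_error(self, domain):
        grid, _ = domain
        tiny = np.zeros(grid.shape, dtype=bool)
        tiny[0, :5] = True
        with pytest.raises(ValueError, match="shortfall"):
            sample_pseudo_absences(tiny, np.arange(10), grid, seed=0)

    @given(seed=st.integers(0, 50))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_count_exact_for_any_seed(self, seed):
        grid = make_grid((0, 3, 0, 3), 0.1)
        valid = np.ones(grid.shape, dtype=bool)
        absences = sample_pseudo_absences(valid, np.arange(30), grid, seed=seed)
        assert absences.size == 60 and np.unique(absences).size == 60


class TestTrainingTable:
    @pytest.fixture(scope="class")
    def mini_stack(self):
        grid = make_grid((0, 1, 0, 1), 0.5)
        stack = PredictorStack(grid)
        for k, name in enumerate(["BIO1", "Urban"]):
            mask = np.zeros(grid.shape, dtype=bool)
            if name == "Urban":
                mask[0, 0] = True  # missing Urban in cell 0
            stack.add_layer(name, Raster(grid, np.full(grid.shape, float(k + 1)), mask))
        return stack

    def test_valid_presence_row(self, mini_stack):
        out = build_training_table(np.array([3]), np.array([1, 2]), mini_stack)
        assert len(out) == 3
        row = out[out.label == 1].iloc[0]
        assert row["BIO1"] == 1.0 and row["Urban"] == 2.0

    def test_missing_predictor_row_dropped(self, mini_stack):
        with pytest.warns(UserWarning, match="missing predictor"):
            out = build_training_table(np.array([0]), np.array([1, 2]), mini_stack)
        assert (out.label == 1).sum() == 0

    def test_label_disjointness_enforced(self, mini_stack):
        with pytest.raises(ValueError, match="both"):
            build_training_table(np.array([1]), np.array([1, 2]), mini_stack)
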