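"""Vital-rate tables, size grids, and lagged compositions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sizeflm.vital_rates import (
    CompositionMatrix,
    build_size_grid,
    callow_cohort_stats,
    composition_for_week,
    development_time,
    development_time_table,
    lagged_composition,
    survival_table,
    survival_trials,
    weekly_compositions,
    weekly_egg_production,
)

from conftest import make_cell, make_worker


class TestSizeGrid:
    def test_equal_width_bins_over_span_range(self):
        grid = build_size_grid([2.0, 4.8, 3.0], 14)
        assert grid.n_bins == 14
        assert np.allclose(np.diff(grid.bin_edges), 0.2)
        assert math.isclose(grid.bin_centers[0], 2.1)

    def test_two_point_symmetric_case(self):
        grid = build_size_grid([3.0, 4.0], 2)
        assert np.allclose(grid.bin_edges, [3.0, 3.5, 4.0])
        assert np.allclose(grid.bin_centers, [3.25, 3.75])

    def test_degenerate_spans_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_size_grid([3.2, 3.2, 3.2], 5)

    def test_last_bin_closed_and_clamping(self):
        grid = build_size_grid([2.0, 4.8], 14)
        assert grid.bin_index(4.8)[0] == 13  # max span in last bin
        assert grid.bin_index(1.5)[0] == 0   # below range clamps
        assert grid.bin_index(5.5)[0] == 13  # above range clamps


class TestEggProduction:
    def test_new_clump_and_prediff_cells_counted(self):
        cells = [make_cell(f"a{i}", [(7, "clump"), (14, "diff")])
                 for i in range(3)]
        cells += [make_cell(f"b{i}", [(7, "prediff"), (14, "cocoon")])
                  for i in range(2)]
        table = weekly_egg_production(cells, {"c1": [0, 7, 14]})
        row = table.df[table.df["week"] == 7].iloc[0]
        assert row["response"] == 5
        assert row["offset_days"] == 7

    def test_zero_count_interval_retained(self):
        table = weekly_egg_production([], {"c1": [0, 7, 14]})
        assert list(table.df["response"]) == [0, 0]
        assert list(table.df["offset_days"]) == [7, 7]

    def test_late_first_stage_not_counted(self):
        cells = [make_cell("a", [(7, "diff"), (14, "cocoon")])]
        table = weekly_egg_production(cells, {"c1": [0, 7, 14]})
        assert table.df["response"].sum() == 0


class TestDevelopmentTime:
    def test_first_clump_to_first_eclosed(self):
        cell = make_cell("a", [(3, "clump"), (10, "diff"), (31, "eclosed")])
        assert development_time(cell) == 28

    def test_consecutive_photos(self):
        cell = make_cell("a", [(0, "clump"), (7, "eclosed")])
        assert development_time(cell) == 7

    def test_missing_clump_start_is_contract_violation(self):
        cell = make_cell("a", [(0, "prediff"), (14, "eclosed")])
        with pytest.raises(ValueError):
            development_time(cell)

    def test_table_rows_carry_development_window(self):
        cell = make_cell("a", [(0, "clump"), (7, "cocoon"), (14, "eclosed")])
        table = development_time_table([cell])
        row = table.df.iloc[0]
        assert (row["window_start"], row["window_end"]) == (0, 14)
        assert row["response"] == 14


class TestSurvivalTrials:
    def test_survived_interval(self):
        assert survival_trials(None, 7, False) == (7, 0)

    def test_died_interval(self):
        assert survival_trials(None, 7, True) == (6, 1)

    def test_single_day_death(self):
        assert survival_trials(None, 1, True) == (0, 1)

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            survival_trials(None, 0, False)

    @given(st.integers(min_value=1, max_value=30), st.booleans())
    @settings(deadline=None, max_examples=50)
    def test_conservation(self, days, died):
        s, f = survival_trials(None, days, died)
        assert s + f == days and s >= 0 and f in (0, 1)

    def test_table_rows_stop_at_death_and_treat_unseen_as_death(self):
        dead = make_cell("a", [(0, "clump"), (7, "diff"), (14, "dead")])
        unseen = make_cell("b", [(0, "clump"), (7, "unseen")])
        alive = make_cell("c", [(0, "clump"), (7, "diff"), (14, "eclosed")])
        table = survival_table([dead, unseen, alive])
        rows = {(r.unit_id): (r.successes, r.failures)
                for r in table.df.itertuples()}
        assert rows["a:7"] == (7, 0) and rows["a:14"] == (6, 1)
        assert rows["b:7"] == (6, 1)
        assert rows["c:7"] == (7, 0) and rows["c:14"] == (7, 0)
        assert "a:21" not in rows  # no trials after death


class TestCallowStats:
    def test_zero_variance_cohort(self):
        workers = [make_worker(f"w{i}", 3.0, {0}) for i in range(3)]
        mean, cv = callow_cohort_stats(workers, {0})
        assert mean == 3.0 and cv == 0.0

    def test_two_worker_cohort_cv(self):
        workers = [make_worker("w1", 2.0, {0}), make_worker("w2", 4.0, {0})]
        mean, cv = callow_cohort_stats(workers, {0})
        assert mean == 3.0
        assert math.isclose(cv, math.sqrt(2) / 3, rel_tol=1e-9)

    def test_empty_cohort_is_missing(self):
        mean, cv = callow_cohort_stats([], {0})
        assert math.isnan(mean) and math.isnan(cv)

    def test_singleton_cohort_mean_only(self):
        mean, cv = callow_cohort_stats([make_worker("w", 3.3, {7})], {7})
        assert mean == 3.3 and math.isnan(cv)

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(deadline=None, max_examples=30)
    def test_cv_scale_invariance(self, scale):
        base = [2.5, 3.1, 3.9, 4.2]
        w1 = [make_worker(f"a{i}", s, {0}) for i, s in enumerate(base)]
        w2 = [make_worker(f"b{i}", s * scale, {0})
              for i, s in enumerate(base)]
        _, cv1 = callow_cohort_stats(w1, {0})
        _, cv2 = callow_cohort_stats(w2, {0})
        assert math.isclose(cv1, cv2, rel_tol=1e-9)


class TestComposition:
    def test_counts_present_workers_per_bin(self, simple_grid):
        workers = [make_worker("w1", 2.1, {7}), make_worker("w2", 2.1, {7}),
                   make_worker("w3", 4.7, {7}),
                   make_worker("w4", 3.0, {14})]  # absent on day 7
        counts = composition_for_week(workers, simple_grid, 7)
        assert counts[0] == 2
        assert counts[-1] == 1
        assert counts.sum() == 3

    def test_no_workers_gives_zero_vector(self, simple_grid):
        assert composition_for_week([], simple_grid, 7).sum() == 0

    def test_row_sums_match_presence(self, simple_grid):
        rng = np.random.default_rng(5)
        workers = [make_worker(f"w{i}", float(rng.uniform(2.2, 4.5)),
                               set(rng.choice([0, 7, 14], 2)))
                   for i in range(30)]
        weekly = weekly_compositions(workers, simple_grid,
                                     {"c1": [0, 7, 14]})
        for uid, row in zip(weekly.unit_ids, weekly.counts):
            day = int(uid.split(":")[1])
            present = sum(1 for w in workers if day in w.presence)
            assert row.sum() == present


class TestLaggedComposition:
    def weekly(self, grid, vecs):
        ids = [f"c1:{7 * i}" for i in range(len(vecs))]
        return CompositionMatrix(ids, np.array(vecs, float), grid, "weekly")

    def test_previous_week_lookup(self):
        grid = build_size_grid([2.0, 4.0], 2)
        weekly = self.weekly(grid, [[1, 0], [2, 1], [3, 3]])
        table = weekly_egg_production([], {"c1": [0, 7, 14]})
        comp, kept = lagged_composition(weekly, table, "previous_week")
        # egg row closing day 7 pairs with the day-0 survey, and so on
        assert np.allclose(comp.counts, [[1, 0], [2, 1]])
        assert list(kept.df["week"]) == [7, 14]

    def test_window_mean_is_elementwise_average(self):
        grid = build_size_grid([2.0, 4.0], 2)
        weekly = self.weekly(grid, [[2, 0], [0, 2]])
        cell = make_cell("a", [(0, "clump"), (7, "eclosed")])
        table = development_time_table([cell])
        comp, kept = lagged_composition(weekly, table,
                                        "development_window_mean")
        assert np.allclose(comp.counts, [[1, 1]])

    def test_constant_weeks_average_to_same_vector(self):
        grid = build_size_grid([2.0, 4.0], 2)
        weekly = self.weekly(grid, [[3, 1]] * 5)
        cell = make_cell("a", [(0, "clump"), (14, "cocoon"), (28, "eclosed")])
        table = development_time_table([cell])
        comp, _ = lagged_composition(weekly, table, "development_window_mean")
        assert np.allclose(comp.counts, [[3, 1]])

    def test_window_mean_within_contributing_range(self):
        rng = np.random.default_rng(9)
        grid = build_size_grid([2.0, 4.0], 3)
        vecs = rng.integers(0, 9, (6, 3)).astype(float)
        weekly = self.weekly(grid, vecs)
        cell = make_cell("a", [(7, "clump"), (21, "cocoon"), (28, "eclosed")])
        table = development_time_table([cell])
        comp, _ = lagged_composition(weekly, table, "development_window_mean")
        window = vecs[1:5]  # surveys on days 7..28
        assert np.all(comp.counts[0] >= window.min(axis=0) - 1e-12)
        assert np.all(comp.counts[0] <= window.max(axis=0) + 1e-12)

    def test_row_without_survey_dropped(self):
        grid = build_size_grid([2.0, 4.0], 2)
        weekly = CompositionMatrix(["c1:0"], np.array([[1.0, 1.0]]), grid,
                                   "weekly")
        table = weekly_egg_production([], {"c1": [0, 7], "c2": [0, 7]})
        comp, kept = lagged_composition(weekly, table, "previous_week")
        assert list(kept.df["colony_id"]) == ["c1"]
        assert comp.counts.shape == (1, 2)

    def test_unknown_convention_rejected(self):
        grid = build_size_grid([2.0, 4.0], 2)
        weekly = self.weekly(grid, [[1, 1]])
        table = weekly_egg_production([], {"c1": [0, 7]})
        with pytest.raises(ValueError, match="convention"):
            lagged_composition(weekly, table, "same_week")
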