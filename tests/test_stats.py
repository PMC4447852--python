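"""Statistics layer: cleaning, aggregation, seasons, GLM, eta squared."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cowtof.stats import (
    add_starting_levels,
    aggregate_daily,
    aggregate_weekly,
    anova_eta2,
    clean_outliers_daily,
    corr_with_significance,
    descriptive_table,
    effect_size_table,
    fit_glm_piecewise,
    group_mean_plot,
    group_means_table,
    overall_r2,
    r2_per_cow,
    season_of_week,
)
from cowtof.tofsim import LongitudinalSimSpec, generate_longitudinal_dataset


class TestOutlierCleaning:
    def test_identical_values_all_kept(self):
        assert list(clean_outliers_daily([5, 5, 5])) == [5, 5, 5]

    def test_gross_outlier_removed(self):
        assert list(clean_outliers_daily([5, 5, 5, 50])) == [5, 5, 5]

    def test_single_value_kept(self):
        assert list(clean_outliers_daily([7.3])) == [7.3]

    def test_moderate_spread_untouched(self):
        vals = [10.0, 10.5, 9.6, 10.2, 9.9]
        assert sorted(clean_outliers_daily(vals)) == sorted(vals)


class TestSeasons:
    @pytest.mark.parametrize("week,season", [
        (50, 1), (49, 1), (52, 1), (1, 1), (9, 1),
        (10, 2), (22, 2), (23, 3), (35, 3), (36, 4), (48, 4),
    ])
    def test_printed_partition(self, week, season):
        assert season_of_week(week) == season

    def test_partition_is_exhaustive_with_four_seasons(self):
        seasons = season_of_week(np.arange(1, 53))
        assert set(seasons) == {1, 2, 3, 4}
        assert len(seasons) == 52

    @pytest.mark.parametrize("week", [0, 53, -3])
    def test_out_of_range_week_is_an_error(self, week):
        with pytest.raises(ValueError):
            season_of_week(week)


class TestCorrelation:
    def test_identity_is_perfect_and_significant(self):
        x = np.arange(20.0)
        r, sig = corr_with_significance(x, x)
        assert r == pytest.approx(1.0)
        assert sig

    def test_independent_series_mostly_ns(self):
        rng = np.random.default_rng(0)
        ns = 0
        for _ in range(20):
            x = rng.normal(size=500)
            y = rng.normal(size=500)
            r, sig = corr_with_significance(x, y)
            assert abs(r) < 0.2
            ns += not sig
        assert ns >= 18

    def test_constant_series_reported_ns(self):
        r, sig = corr_with_significance(np.arange(10.0), np.full(10, 3.0))
        assert np.isnan(r) and not sig

    def test_missing_values_dropped_pairwise(self):
        x = np.array([1.0, 2, 3, np.nan, 5])
        y = np.array([2.0, 4, 6, 8, np.nan])
        r, sig = corr_with_significance(x, y)
        assert r == pytest.approx(1.0)


class TestPiecewiseGlm:
    @staticmethod
    def _design(rng, n=500):
        return np.column_stack([
            np.ones(n), rng.uniform(0, 40, n), rng.normal(10, 2, n)
        ])

    def test_linear_data_gives_r2_one_for_any_knot(self):
        rng = np.random.default_rng(1)
        X = self._design(rng)
        y = X @ np.array([2.0, 0.5, 1.0])
        for grid in (None, [np.median(y)], [y.min() + 1, y.max() - 1]):
            assert fit_glm_piecewise(y, X, grid).r2 == pytest.approx(1.0)

    def test_kinked_link_recovered(self):
        rng = np.random.default_rng(3)
        X = self._design(rng)
        b = np.array([2.0, 0.5, 1.0])
        eta = X @ b
        knot, inv_slope = float(np.median(eta)), 0.4
        y = np.where(eta <= knot, eta, knot + (eta - knot) * inv_slope)
        y = y + rng.normal(0, 0.1, y.size)
        grid = np.quantile(y, np.arange(0.1, 0.95, 0.1))
        fit = fit_glm_piecewise(y, X, grid)
        assert abs(fit.knot - knot) <= np.diff(grid).max()
        assert np.all(np.abs(fit.coefficients - b) <= 0.1 * np.abs(b))
        assert fit.slope2 == pytest.approx(1 / inv_slope, rel=0.1)

    def test_pure_noise_gives_small_r2(self):
        rng = np.random.default_rng(5)
        X = self._design(rng)
        y = rng.normal(size=500)
        assert fit_glm_piecewise(y, X).r2 < 0.1

    def test_singular_design_is_an_error(self):
        X = np.column_stack([np.ones(50), np.ones(50)])
        with pytest.raises(np.linalg.LinAlgError):
            fit_glm_piecewise(np.random.default_rng(0).normal(size=50), X)

    def test_r2_stays_in_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            X = self._design(rng, n=80)
            y = rng.normal(size=80) * rng.uniform(0.1, 5)
            r2 = fit_glm_piecewise(y, X).r2
            assert 0.0 <= r2 <= 1.0


class TestPerCowR2:
    def _records(self, seed=0, resid=0.0, n_cows=4, n_weeks=20):
        spec = LongitudinalSimSpec(
            n_cows=n_cows, n_weeks=n_weeks, cow_sd=1.0, resid_sd=resid,
            seed=seed, baselines={"HH": 40.0},
        )
        return generate_longitudinal_dataset(spec)

    def test_exactly_linear_trait_gives_one(self):
        df = self._records(resid=0.0)
        df["HH"] = df["HH"] + 0.8 * df["lactation_week"]
        r2 = r2_per_cow(df, "HH", min_weeks=16)
        assert np.allclose(r2, 1.0)

    def test_constant_plus_noise_gives_near_zero(self):
        df = self._records(seed=2, resid=1.0, n_cows=10, n_weeks=40)
        r2 = r2_per_cow(df, "HH", min_weeks=16)
        assert r2.mean() < 0.25

    def test_minimum_over_noise_herd_is_near_zero(self):
        df = self._records(seed=3, resid=1.0, n_cows=20, n_weeks=30)
        r2 = r2_per_cow(df, "HH", min_weeks=16)
        assert r2.min() < 0.1

    def test_short_histories_skipped(self):
        df = self._records(n_weeks=10)
        assert len(r2_per_cow(df, "HH", min_weeks=16)) == 0

    def test_overall_model_uses_starting_level(self):
        df = self._records(seed=5, resid=0.2, n_cows=10, n_weeks=30)
        fit = overall_r2(df, "HH")
        assert 0.0 <= fit.r2 <= 1.0


class TestEta2:
    def test_disjoint_constant_groups_give_one(self):
        eta2, sig = anova_eta2([0, 0, 1, 1], ["a", "a", "b", "b"])
        assert eta2 == pytest.approx(1.0)
        assert sig

    def test_equal_group_means_give_zero(self):
        eta2, _ = anova_eta2([1, 2, 1, 2], ["a", "a", "b", "b"])
        assert eta2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # groups {1,2} and {3,4}: SSB = 4, SST = 5
        eta2, _ = anova_eta2([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert eta2 == pytest.approx(0.8)

    def test_single_group_is_an_error(self):
        with pytest.raises(ValueError):
            anova_eta2([1.0, 2.0], ["a", "a"])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=6, max_size=40),
        st.integers(2, 4),
        st.integers(0, 10_000),
    )
    def test_matches_brute_force_on_random_instances(self, values, k, seed):
        values = np.asarray(values)
        rng = np.random.default_rng(seed)
        groups = rng.integers(0, k, size=values.size)
        if len(np.unique(groups)) < 2 or np.ptp(values) == 0:
            return
        eta2, _ = anova_eta2(values, groups)
        grand = values.mean()
        sst = ((values - grand) ** 2).sum()
        ssw = sum(
            ((values[groups == g] - values[groups == g].mean()) ** 2).sum()
            for g in np.unique(groups)
        )
        assert eta2 == pytest.approx(1 - ssw / sst, abs=1e-12)


class TestAggregation:
    def _frame_table(self):
        rows = []
        for day, values in (("2011-07-11", [2.0, 2.0]), ("2011-07-13", [4.0])):
            for v in values:
                rows.append({
                    "cow_id": "c1", "date": day, "HH": v, "DL": v / 2,
                })
        return pd.DataFrame(rows)

    def test_two_days_average_to_their_mean(self):
        daily = aggregate_daily(self._frame_table(), trait_cols=("HH", "DL"))
        weekly = aggregate_weekly(daily, trait_cols=("HH", "DL"))
        assert len(weekly) == 1
        assert weekly.loc[0, "HH"] == pytest.approx(3.0)

    def test_single_day_passes_through(self):
        df = pd.DataFrame(
            [{"cow_id": "c1", "date": "2011-07-11", "HH": 7.0}]
        )
        daily = aggregate_daily(df, trait_cols=("HH",))
        weekly = aggregate_weekly(daily, trait_cols=("HH",))
        assert weekly.loc[0, "HH"] == 7.0

    def test_twenty_week_cow_yields_twenty_records(self):
        dates = pd.date_range("2011-01-03", periods=20, freq="7D")
        df = pd.DataFrame({
            "cow_id": "c1", "date": dates.astype(str), "HH": np.arange(20.0),
        })
        daily = aggregate_daily(df, trait_cols=("HH",))
        weekly = aggregate_weekly(daily, trait_cols=("HH",))
        assert len(weekly) == 20

    def test_never_invents_records(self):
        df = self._frame_table()
        daily = aggregate_daily(df, trait_cols=("HH", "DL"))
        weekly = aggregate_weekly(daily, trait_cols=("HH", "DL"))
        assert len(weekly) <= df.groupby(["cow_id", "date"]).ngroups

    def test_reference_join_brings_bft(self):
        daily = aggregate_daily(self._frame_table(), trait_cols=("HH", "DL"))
        ref = pd.DataFrame([
            {"cow_id": "c1", "date": "2011-07-12", "BFT": 11.0},
        ])
        weekly = aggregate_weekly(daily, ref, trait_cols=("HH", "DL"))
        assert weekly.loc[0, "BFT"] == 11.0

    def test_outliers_cleaned_before_daily_mean(self):
        df = pd.DataFrame([
            {"cow_id": "c1", "date": "2011-07-11", "HH": v}
            for v in (5.0, 5.0, 5.0, 50.0)
        ])
        daily = aggregate_daily(df, trait_cols=("HH",))
        assert daily.loc[0, "HH"] == pytest.approx(5.0)


class TestGroupMeans:
    def _seasonal_records(self):
        spec = LongitudinalSimSpec(
            n_cows=12, n_weeks=52, cow_sd=0.3, resid_sd=0.3,
            season_effects=(3.0, 1.0, -1.0, -3.0), start_iso_week=1, seed=6,
            baselines={"HH": 40.0},
        )
        return generate_longitudinal_dataset(spec)

    def test_season_means_order_matches_designed_effects(self, tmp_path):
        records = self._seasonal_records()
        table = group_mean_plot(records, "HH", "season", tmp_path / "p.png")
        assert len(table) == 4
        means = table.sort_values("season")["mean"].to_numpy()
        assert np.all(np.diff(means) < 0)
        assert (tmp_path / "p.png").exists()

    def test_single_group_single_point(self):
        df = pd.DataFrame({"season": [1, 1], "HH": [4.0, 6.0]})
        table = group_means_table(df, "HH", "season")
        assert len(table) == 1

    def test_zero_variance_group_has_zero_width_interval(self):
        df = pd.DataFrame({"season": [1, 1, 2, 2], "HH": [4.0, 4.0, 5.0, 6.0]})
        table = group_means_table(df, "HH", "season").set_index("season")
        assert table.loc[1, "ci_lo"] == table.loc[1, "ci_hi"] == 4.0


class TestTables:
    def test_descriptive_and_effect_tables_cover_traits(self):
        spec = LongitudinalSimSpec(
            n_cows=10, n_weeks=20, cow_sd=1.0, resid_sd=0.5, seed=8,
        )
        records = add_starting_levels(generate_longitudinal_dataset(spec))
        desc = descriptive_table(records, min_weeks=16)
        assert {"trait", "N", "min", "max", "mean", "std", "R2"} <= set(desc.columns)
        assert "BFT" in set(desc["trait"])
        eff = effect_size_table(records)
        cow_eta = eff.set_index("trait")["eta2_cow"]
        assert (cow_eta.dropna() > 0.3).all()
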