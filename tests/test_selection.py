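import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from snowsel.grid import Grid
from snowsel.selection import (
    ContingencyTable,
    DielPeriod,
    PolarDayNightError,
    availability_fraction,
    classify_diel,
    diel_selection,
    expected_under_proportional,
    odds_ratio,
    overlay_positions,
    select_against_availability,
    solar_times,
)
from snowsel.tracks import Track


def make_track(xs, ys, start="2015-01-15T00:00:00"):
    n = len(xs)
    times = np.datetime64(start) + np.arange(n) * np.timedelta64(3, "h")
    return Track("a", times.astype("datetime64[ns]"), xs, ys)


def mask_grid(arr, cell=1.0):
    arr = np.asarray(arr, dtype=float)
    return Grid(arr, origin_x=0.0, origin_y=arr.shape[0] * cell, cell=cell)


class TestOverlay:
    def test_toy_two_of_three_on_mask(self):
        mask = mask_grid([[1, 1, 0]])
        trk = make_track([0.5, 1.5, 2.5], [0.5, 0.5, 0.5])
        on, off, excluded = overlay_positions([trk], mask)
        assert (on, off, excluded) == (2, 1, 0)

    def test_all_on_and_all_off(self):
        trk = make_track([0.5, 1.5], [0.5, 0.5])
        assert overlay_positions([trk], mask_grid([[1, 1]]))[:2] == (2, 0)
        assert overlay_positions([trk], mask_grid([[0, 0]]))[:2] == (0, 2)

    def test_outside_positions_excluded_with_count(self):
        mask = mask_grid([[1, 0]])
        trk = make_track([0.5, 50.0], [0.5, 0.5])
        on, off, excluded = overlay_positions([trk], mask)
        assert (on, off, excluded) == (1, 0, 1)

    def test_all_outside_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            overlay_positions([make_track([99.0], [99.0])], mask_grid([[1]]))


class TestExpected:
    @pytest.mark.parametrize(
        "n,f,expected", [(100, 0.25, 25.0), (100, 0.0, 0.0), (188942, 0.092, 17382.664)]
    )
    def test_proportional_expectation(self, n, f, expected):
        assert expected_under_proportional(n, f) == pytest.approx(expected)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            expected_under_proportional(10, 1.2)


class TestOddsRatio:
    def test_small_table_direct_arithmetic(self):
        res = odds_ratio(ContingencyTable(3, 7, 2, 8))
        assert res.odds_ratio == pytest.approx(12 / 7, abs=1e-12)

    def test_equal_proportions_or_one(self):
        res = odds_ratio(ContingencyTable(10, 30, 100, 300))
        assert res.odds_ratio == pytest.approx(1.0)

    def test_zero_cell_requires_explicit_correction(self):
        t = ContingencyTable(0, 10, 5, 5)
        with pytest.raises(ValueError, match="haldane"):
            odds_ratio(t)
        res = odds_ratio(t, haldane=True)
        assert res.odds_ratio == pytest.approx((0.5 / 10.5) / (5.5 / 5.5))

    def test_ci_brackets_or_and_p_symmetry(self):
        res = odds_ratio(ContingencyTable(30, 70, 20, 80))
        assert res.ci_low <= res.odds_ratio <= res.ci_high
        assert 0 <= res.p_value <= 1

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(*[st.integers(1, 50)] * 4))
    def test_matches_statsmodels_wald_interval(self, cells):
        import statsmodels.api as sm

        a, b, c, d = cells
        res = odds_ratio(ContingencyTable(a, b, c, d))
        t22 = sm.stats.Table2x2(np.array([[a, b], [c, d]]))
        assert res.odds_ratio == pytest.approx(t22.oddsratio, rel=1e-12)
        lo, hi = t22.oddsratio_confint(0.05)
        assert res.ci_low == pytest.approx(lo, rel=1e-9)
        assert res.ci_high == pytest.approx(hi, rel=1e-9)


class TestSolarTimes:
    def test_equator_equinox_sunrise_near_six(self):
        sunrise, sunset = solar_times("2015-03-20", lat=0.0, lon=0.0)
        six = pd.Timestamp("2015-03-20T06:00:00")
        assert abs((sunrise - six).total_seconds()) < 600
        assert sunrise < sunset

    def test_high_latitude_december_short_day(self):
        sunrise, sunset = solar_times("2015-12-15", lat=60.0, lon=7.5)
        assert (sunset - sunrise).total_seconds() < 7 * 3600
        assert sunrise < sunset

    def test_polar_night_flagged(self):
        with pytest.raises(PolarDayNightError):
            solar_times("2015-12-21", lat=78.0, lon=15.0)

    def test_polar_day_flagged(self):
        with pytest.raises(PolarDayNightError):
            solar_times("2015-06-21", lat=78.0, lon=15.0)


class TestDielClassification:
    sunrise = pd.Timestamp("2015-01-15T06:00:00")
    sunset = pd.Timestamp("2015-01-15T18:00:00")

    @pytest.mark.parametrize(
        "t,expected",
        [
            ("12:00", DielPeriod.DAY),
            ("18:30", DielPeriod.EVENING),
            ("17:00", DielPeriod.EVENING),  # sunset-1h boundary, right-open
            ("07:00", DielPeriod.DAY),      # sunrise+1h boundary
            ("05:00", DielPeriod.MORNING),  # sunrise-1h boundary
            ("06:59", DielPeriod.MORNING),
            ("19:00", DielPeriod.NIGHT),    # sunset+1h boundary
            ("02:00", DielPeriod.NIGHT),
        ],
    )
    def test_window_assignment(self, t, expected):
        ts = pd.Timestamp(f"2015-01-15T{t}:00")
        assert classify_diel(ts, self.sunrise, self.sunset) is expected

    def test_every_minute_maps_to_exactly_one_period(self):
        minutes = pd.date_range("2015-01-15", periods=24 * 60, freq="min")
        counts = {p: 0 for p in DielPeriod}
        for ts in minutes:
            counts[classify_diel(ts, self.sunrise, self.sunset)] += 1
        assert sum(counts.values()) == 24 * 60
        # morning and evening are exactly 2 h; day = daylength - 2 h
        assert counts[DielPeriod.MORNING] == 120
        assert counts[DielPeriod.EVENING] == 120
        assert counts[DielPeriod.DAY] == 12 * 60 - 120

    def test_inverted_sun_times_rejected(self):
        with pytest.raises(PolarDayNightError):
            classify_diel(pd.Timestamp("2015-01-15T12:00"), self.sunset, self.sunrise)


class TestDielSelection:
    def test_per_period_observed_sums_to_total(self, bundle):
        mask = bundle.snow_frac_true.like(
            (np.nan_to_num(bundle.snow_frac_true.values) >= 0.3).astype(float)
        )
        avail = availability_fraction(mask)
        df = diel_selection(bundle.tracks, mask, avail, lat=60.0, lon=7.5)
        total_on, _, _ = overlay_positions(bundle.tracks, mask)
        assert df.loc[df["defined"], "observed_on"].sum() == total_on

    def test_evening_boosted_use_shows_higher_evening_excess(self):
        # hand-built positions: evening fixes land on the patch 3x as often
        mask = mask_grid(np.concatenate([np.ones((10, 2)), np.zeros((10, 8))], axis=1))
        rng = np.random.default_rng(1)
        times = pd.date_range("2015-01-15", periods=2000, freq="3h")
        xs, ys = [], []
        for ts in times:
            evening = 16 <= ts.hour < 19
            p_on = 0.6 if evening else 0.2
            on = rng.uniform() < p_on
            xs.append(rng.uniform(0, 2) if on else rng.uniform(2, 10))
            ys.append(rng.uniform(0.01, 10))
        trk = Track("a", times.values, np.array(xs), np.array(ys))
        df = diel_selection([trk], mask, availability_fraction(mask), lat=60.0, lon=7.5)
        df = df.set_index("period")
        assert df.loc["evening", "excess_pct"] > df.loc["day", "excess_pct"]


def test_select_against_availability_recovers_preference(bundle):
    mask = bundle.snow_frac_true.like(
        (np.nan_to_num(bundle.snow_frac_true.values) >= 0.3).astype(float)
    )
    res = select_against_availability(bundle.tracks, mask)
    # tracks were simulated with a positive snow-free preference
    assert res.odds_ratio > 1.0
    assert res.ci_low <= res.odds_ratio <= res.ci_high
    assert res.ratio == pytest.approx(
        res.observed_on / res.expected_on
    )
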