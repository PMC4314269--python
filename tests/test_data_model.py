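"""Input containers, range handling and the counting-process expansion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kappaipm.data_model import (
    CountSeries,
    DataValidationError,
    PeriodMap,
    SurvivalRecord,
    decimal_year,
    derive_counts,
    derive_recruits,
    expand_records,
    read_counts,
    read_recruits,
    read_telemetry,
    standardize_log_abundance,
    write_telemetry,
)


class TestDeriveCounts:
    def test_wolf_range_midpoint_and_quarter_range(self):
        # a 2012-style range of 815-880 animals
        cs = derive_counts([(2011, 700, 750), (2012, 815, 880)])
        assert cs.n_mid[-1] == pytest.approx(847.5)
        assert (880 - 815) / 4 == pytest.approx(16.25)
        assert cs.v == pytest.approx(((750 - 700) / 4 + 16.25) / 2)

    def test_equal_ranges_give_common_quarter_width(self):
        cs = derive_counts([(1, 80, 100), (2, 40, 60)])
        assert list(cs.n_mid) == [90.0, 50.0]
        assert cs.v == pytest.approx(5.0)

    def test_log_scale_error_is_mean_relative_quarter_range(self):
        cs = derive_counts([(1, 80, 100), (2, 40, 60)], error_scale="log")
        assert cs.v == pytest.approx((5.0 / 90.0 + 5.0 / 50.0) / 2)

    def test_degenerate_ranges_rejected(self):
        with pytest.raises(DataValidationError, match="v > 0"):
            derive_counts([(1, 100, 100)])

    def test_gap_in_years_names_the_gap(self):
        with pytest.raises(DataValidationError, match="1991 and 1993"):
            derive_counts([(1991, 10, 12), (1993, 11, 13)])

    def test_low_above_high_rejected(self):
        with pytest.raises(DataValidationError, match="exceeds"):
            derive_counts([(1, 12, 10)])

    def test_sorted_output(self):
        cs = derive_counts([(2, 40, 60), (1, 80, 100)])
        assert list(cs.year) == [1, 2]

    def test_half_integer_midpoints_not_rounded(self):
        cs = derive_counts([(1, 10, 13), (2, 11, 14)])
        assert cs.n_mid[0] == pytest.approx(11.5)


class TestRoundTrips:
    def test_counts_csv_round_trip_exact(self, tmp_path):
        cs = derive_counts([(1, 80.25, 100.5), (2, 40.0, 60.0)])
        path = tmp_path / "counts.csv"
        cs.write_csv(path)
        back = read_counts(path)
        assert np.array_equal(back.year, cs.year)
        assert np.array_equal(back.n_low, cs.n_low)
        assert np.array_equal(back.n_high, cs.n_high)
        assert back.v == cs.v

    def test_recruits_csv_round_trip_exact(self, tmp_path):
        rs = derive_recruits([(2, 10, 14), (3, 12, 17)])
        path = tmp_path / "recruits.csv"
        rs.write_csv(path)
        back = read_recruits(path)
        assert np.array_equal(back.r_mid, rs.r_mid)

    def test_telemetry_csv_round_trip_exact(self, tmp_path):
        recs = [
            SurvivalRecord("w1", 1.2345678901, 2.5, 1),
            SurvivalRecord("w2", 1.5, 3.0000001, 0),
        ]
        path = tmp_path / "telemetry.csv"
        write_telemetry(path, recs)
        back = read_telemetry(path)
        assert back == recs

    def test_iso_dates_convert_to_decimal_years(self):
        assert decimal_year("2001-01-01") == pytest.approx(2001.0)
        assert decimal_year("2001-07-02") == pytest.approx(2001.0 + 182 / 365, abs=1e-9)
        assert decimal_year(1999.25) == 1999.25


class TestSurvivalRecordValidation:
    def test_entry_must_precede_exit(self):
        with pytest.raises(DataValidationError):
            SurvivalRecord("x", 2.0, 2.0, 1)

    def test_event_indicator_binary(self):
        with pytest.raises(DataValidationError):
            SurvivalRecord("x", 1.0, 2.0, 2)


class TestExpandRecords:
    def test_record_spanning_three_years_splits_and_places_event(self):
        rec = SurvivalRecord("w", 2001.2, 2003.4, 1)
        rt = expand_records([rec], span=(2001, 2004), ds=1 / 12, year_start="01-01")
        years_at_risk = np.unique(rt.year_of_interval[rt.Y[0] == 1])
        assert list(years_at_risk) == [2001, 2002, 2003]
        j = np.flatnonzero(rt.dM[0])[0]
        assert rt.grid[j] <= 2003.4 < rt.grid[j + 1]
        assert rt.total_events == 1

    def test_half_year_record_covers_six_monthly_intervals(self):
        rec = SurvivalRecord("w", 2000.0, 2000.5, 0)
        rt = expand_records([rec], span=(2000, 2001), ds=1 / 12, year_start="01-01")
        assert rt.Y[0].sum() == 6
        assert rt.dM.sum() == 0

    def test_event_on_interval_boundary_lands_in_preceding_interval(self):
        rec = SurvivalRecord("w", 2000.0, 2000.25, 1)
        rt = expand_records([rec], span=(2000, 2001), ds=0.25, year_start="01-01")
        assert rt.dM[0, 0] == 1 and rt.Y[0, 0] == 1

    def test_total_events_equals_death_records(self):
        recs = [
            SurvivalRecord(f"w{i}", 2000.1 + 0.1 * i, 2001.0 + 0.2 * i, i % 2)
            for i in range(6)
        ]
        rt = expand_records(recs, span=(2000, 2003), ds=1 / 12, year_start="01-01")
        assert rt.total_events == sum(r.delta for r in recs)

    def test_record_outside_span_rejected(self):
        with pytest.raises(DataValidationError, match="outside"):
            expand_records(
                [SurvivalRecord("w", 1999.5, 2000.5, 0)],
                span=(2000, 2001), ds=1 / 12, year_start="01-01",
            )

    def test_uneven_grid_width_rejected(self):
        with pytest.raises(DataValidationError, match="evenly"):
            expand_records(
                [SurvivalRecord("w", 2000.1, 2000.6, 0)],
                span=(2000, 2001), ds=0.3, year_start="01-01",
            )

    def test_september_year_start_shifts_boundaries(self):
        rec = SurvivalRecord("w", 2000.8, 2001.5, 0)
        rt = expand_records([rec], span=(2000, 2002), ds=1 / 12, year_start="09-01")
        assert rt.grid[0] == pytest.approx(2000 + 243 / 365)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=2000.0, max_value=2004.8),
                st.floats(min_value=0.05, max_value=3.0),
                st.booleans(),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_exposure_matches_brute_force_overlap(self, raw):
        records = []
        for i, (a, dur, died) in enumerate(raw):
            b = min(a + dur, 2004.99)
            if b - a < 1e-6:
                continue
            records.append(SurvivalRecord(f"w{i}", a, b, int(died)))
        if not records:
            return
        ds = 1 / 12
        rt = expand_records(records, span=(2000, 2005), ds=ds, year_start="01-01")
        # brute force: overlap of [a, b] with each interval, counted when > 0
        for i, r in enumerate(records):
            expected = sum(
                1
                for j in range(rt.n_intervals)
                if min(r.b, rt.grid[j + 1]) - max(r.a, rt.grid[j]) > 1e-12
            )
            assert rt.Y[i].sum() == expected
            assert abs(rt.Y[i].sum() * ds - (r.b - r.a)) <= 2 * ds

    def test_total_exposure_close_to_sum_of_durations(self):
        rng = np.random.default_rng(5)
        recs = [
            SurvivalRecord(f"w{i}", a := 2000 + 3 * rng.random(), a + 0.1 + rng.random(), 0)
            for i in range(40)
        ]
        rt = expand_records(recs, span=(2000, 2005), ds=1 / 12, year_start="01-01")
        total = sum(r.b - r.a for r in recs)
        assert abs(rt.total_exposure - total) <= len(recs) * rt.ds


class TestStandardize:
    def test_hand_computed_two_level_series(self):
        z = standardize_log_abundance([np.e, np.e, np.e**3, np.e**3])
        assert np.allclose(z, [-1.0, -1.0, 1.0, 1.0])

    def test_sample_sd_variant(self):
        z = standardize_log_abundance([np.e, np.e, np.e**3, np.e**3], ddof=1)
        assert np.allclose(z, np.array([-1, -1, 1, 1]) * np.sqrt(3) / 2)

    @given(
        st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=3, max_size=30),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_zero_mean_unit_sd_and_scale_invariance(self, values, c):
        if len(set(values)) < 2:
            return
        z = standardize_log_abundance(values)
        assert abs(z.mean()) < 1e-10
        assert abs(z.std() - 1.0) < 1e-10
        assert np.allclose(z, standardize_log_abundance(np.asarray(values) * c))

    def test_constant_series_rejected(self):
        with pytest.raises(DataValidationError, match="constant"):
            standardize_log_abundance([5.0, 5.0, 5.0])


class TestPeriodMap:
    def test_three_recovery_periods(self):
        pm = PeriodMap((17, 24))
        years = np.arange(2, 33)
        periods = pm.period_of_year(years)
        assert periods[years < 17].max() == 0
        assert set(periods[(years >= 17) & (years < 24)]) == {1}
        assert set(periods[years >= 24]) == {2}
        assert pm.n_periods == 3

    def test_unordered_breakpoints_rejected(self):
        with pytest.raises(DataValidationError):
            PeriodMap((24, 17))
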