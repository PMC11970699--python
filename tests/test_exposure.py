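"""Calendar arithmetic, monsoon overlap, design rows and influx integration."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import campmort as cm
from campmort.exposure import InfluxSeries, person_time_from_influx

D = dt.date

#: printed interval durations of the bundled table, in file order
BUNDLED_DURATIONS = [153, 8, 12, 17, 62, 30, 5, 217, 25, 199, 16, 61, 230, 230,
                     9, 13, 21]


class TestDurationDays:
    def test_reproduces_all_bundled_durations(self, records):
        got = [cm.duration_days(r.start_date, r.end_date) for r in records]
        assert got == BUNDLED_DURATIONS

    @pytest.mark.parametrize(
        "start, end, expected",
        [
            (D(1971, 7, 1), D(1971, 11, 30), 153),
            (D(1971, 6, 1), D(1971, 12, 16), 199),
            (D(1971, 6, 1), D(1971, 6, 1), 1),
        ],
    )
    def test_inclusive_count(self, start, end, expected):
        assert cm.duration_days(start, end) == expected

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            cm.duration_days(D(1971, 6, 2), D(1971, 6, 1))


class TestMonsoonFraction:
    def test_banjetia_under_published_convention(self, records, config):
        banjetia = records[9]
        cfg = config.replace(overlap_convention="paper")
        assert cm.monsoon_fraction(banjetia, cfg) == pytest.approx(121 / 199)
        assert cm.monsoon_fraction(banjetia, cfg) == pytest.approx(0.608, abs=5e-4)

    def test_banjetia_inclusive_convention(self, records, config):
        assert cm.monsoon_fraction(records[9], config) == pytest.approx(122 / 199)

    def test_interval_inside_window_is_one(self, records, config):
        barasat_hospital = records[8]  # 01/07-25/07, all causes
        assert cm.monsoon_fraction(barasat_hospital, config) == 1.0
        cfg = config.replace(overlap_convention="paper")
        assert cm.monsoon_fraction(barasat_hospital, cfg) == 1.0

    def test_cause_label_governs_monsoon_rows(self, records, config):
        jambu = records[14]  # cyclone row, late Oct/Nov, outside the window
        assert jambu.end_date > config.monsoon_end
        assert cm.monsoon_fraction(jambu, config) == 1.0

    def test_general_rows_are_zero(self, records, config):
        salt_lake = records[0]
        assert cm.monsoon_fraction(salt_lake, config) == 0.0

    @given(
        start_off=st.integers(0, 250),
        length=st.integers(1, 100),
        cause=st.sampled_from(list(cm.CauseClass)),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_fraction_always_in_unit_interval(self, start_off, length, cause):
        start = D(1971, 3, 25) + dt.timedelta(days=start_off)
        end = min(start + dt.timedelta(days=length - 1), D(1971, 12, 16))
        rec = cm.CampRecord(
            camp_name="x", state="s", population=1000, deaths=0,
            start_date=start, end_date=end, cause_class=cause,
        )
        for conv in ("inclusive", "paper"):
            cfg = cm.StudyConfig(overlap_convention=conv)
            assert 0.0 <= cm.monsoon_fraction(rec, cfg) <= 1.0


class TestDesignRow:
    def test_salt_lake_person_time(self, design):
        row = design[0]
        assert row.person_time == pytest.approx(26.01)
        assert row.x_b == pytest.approx(26.01)
        assert row.x_m == 0.0

    def test_kalyani_monsoon_exposure(self, design):
        kalyani = design[5]
        assert kalyani.x_b == 0.0
        assert kalyani.x_m == pytest.approx(1.5)  # 50,000 x 30 days / 1e6

    def test_barasat_jail_mixed_exposure(self, design):
        jail = design[7]  # 3,000 people, 217 days, all causes
        assert jail.x_b == pytest.approx(0.651)
        assert jail.x_m == pytest.approx(0.651 * 122 / 217)

    def test_exposure_rule_per_cause_class(self, records, design, config):
        for rec, row in zip(records, design):
            pt = cm.person_time(rec)
            if rec.cause_class is cm.CauseClass.GENERAL:
                assert (row.x_b, row.x_m) == (pt, 0.0)
            elif rec.cause_class is cm.CauseClass.MONSOON_EXCESS:
                assert (row.x_b, row.x_m) == (0.0, pt)
            else:
                assert row.x_b == pt
                assert row.x_m == pytest.approx(pt * row.monsoon_fraction)


def _series(days, counts, start=D(1971, 4, 10)):
    return InfluxSeries(
        tuple(start + dt.timedelta(days=int(d)) for d in days),
        tuple(float(c) for c in counts),
    )


def _daily_step_oracle(series, window=None):
    """Brute-force: sample the interpolated curve at small steps and sum."""
    t0 = series.dates[0]
    x = np.array([(d - t0).days for d in series.dates], float)
    y = np.array(series.cumulative, float)
    if window is None:
        a, b = x[0], x[-1]
    else:
        a, b = (window[0] - t0).days, (window[1] - t0).days
    grid = np.linspace(a, b, int((b - a) * 200) + 1)
    vals = np.interp(grid, x, y)
    return np.trapezoid(vals, grid) / 1e6


class TestInfluxIntegration:
    def test_constant_population_rectangle(self):
        s = _series([0, 100], [1_000_000, 1_000_000])
        assert person_time_from_influx(s) == pytest.approx(100.0)

    def test_linear_ramp_triangle(self):
        s = _series([0, 100], [0, 1_000_000])
        assert person_time_from_influx(s) == pytest.approx(50.0)

    def test_subwindow(self):
        s = _series([0, 100], [1_000_000, 1_000_000])
        w = (D(1971, 4, 20), D(1971, 4, 30))
        assert person_time_from_influx(s, w) == pytest.approx(10.0)

    def test_window_outside_span_rejected(self):
        s = _series([0, 100], [0, 1_000_000])
        with pytest.raises(ValueError):
            person_time_from_influx(s, (D(1971, 4, 1), D(1971, 4, 30)))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            InfluxSeries((D(1971, 4, 10),), (0.0,))

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            _series([0, 10, 20], [100, 50, 200])

    @given(
        data=st.lists(
            st.tuples(st.integers(1, 20), st.floats(0, 1e6)),
            min_size=2, max_size=8,
        ),
        split=st.floats(0.1, 0.9),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_additive_over_disjoint_windows_and_matches_oracle(self, data, split):
        days = np.cumsum([0] + [d for d, _ in data])
        counts = np.cumsum([0.0] + [c for _, c in data])
        s = _series(list(days), list(counts))
        total = person_time_from_influx(s)
        mid_day = int(days[-1] * split)
        mid = s.dates[0] + dt.timedelta(days=mid_day)
        left = person_time_from_influx(s, (s.dates[0], mid))
        right = person_time_from_influx(s, (mid, s.dates[-1]))
        assert left + right == pytest.approx(total, rel=1e-9, abs=1e-9)
        oracle = _daily_step_oracle(s)
        assert total == pytest.approx(oracle, rel=1e-3, abs=1e-6)
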