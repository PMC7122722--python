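import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fireardl.dataset import (
    TimeSeriesDataset,
    difference,
    drop_non_fire_season,
    load_timeseries,
    log_transform,
    write_timeseries,
)


def _csv(tmp_path, frame, name="data.csv"):
    p = tmp_path / name
    frame.to_csv(p, index=False)
    return p


def _monthly_frame(n=216, start="2001-01", cols=("area_burned", "wind")):
    rng = np.random.default_rng(0)
    dates = pd.period_range(start, periods=n, freq="M").astype(str)
    data = {"date": dates}
    for c in cols:
        data[c] = rng.uniform(1, 10, n)
    return pd.DataFrame(data)


class TestLoad:
    def test_full_study_window(self, tmp_path):
        ds = load_timeseries(_csv(tmp_path, _monthly_frame()))
        assert ds.n_obs == 216
        assert str(ds.time_index[0]) == "2001-01"
        assert str(ds.time_index[-1]) == "2018-12"

    def test_duplicate_month_is_error(self, tmp_path):
        f = _monthly_frame(n=12)
        f.loc[5, "date"] = "2001-04"
        with pytest.raises(ValueError, match="duplicate"):
            load_timeseries(_csv(tmp_path, f))

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        f = _monthly_frame(n=12)
        f["wind"] = f["wind"].astype(object)
        f.loc[3, "wind"] = "gale"
        with pytest.raises(ValueError, match=r"wind.*row 3"):
            load_timeseries(_csv(tmp_path, f))

    def test_empty_table_is_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("date,wind\n")
        with pytest.raises(ValueError):
            load_timeseries(p)

    def test_schema_renaming_gives_identical_dataset(self, tmp_path):
        f = _monthly_frame(cols=("area_burned", "t_max"))
        renamed = f.rename(columns={"t_max": "Tmax"})
        a = load_timeseries(_csv(tmp_path, f, "a.csv"))
        b = load_timeseries(_csv(tmp_path, renamed, "b.csv"), schema={"t_max": "Tmax"})
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_rows_outside_window_dropped_and_missing_rows_dropped(self, tmp_path):
        f = _monthly_frame(n=240, start="2000-01")
        f.loc[30, "wind"] = np.nan
        ds = load_timeseries(_csv(tmp_path, f))
        # 2000 dropped by window; one NaN row dropped
        assert ds.n_obs == 216 - 1

    def test_round_trip_preserves_values_and_index(self, tmp_path):
        ds = load_timeseries(_csv(tmp_path, _monthly_frame()))
        out = tmp_path / "out.csv"
        write_timeseries(ds, out)
        ds2 = load_timeseries(out)
        pd.testing.assert_frame_equal(ds.frame, ds2.frame)


class TestLogTransform:
    def test_known_values(self, tmp_path):
        idx = pd.period_range("2005-01", periods=3, freq="M")
        frame = pd.DataFrame({"wind": [1.0, np.e, np.e**2]}, index=idx)
        ds = TimeSeriesDataset(frame=frame)
        out = log_transform(ds, offsets={"wind": 0.0})
        np.testing.assert_allclose(out.series("wind"), [0.0, 1.0, 2.0], atol=1e-15)
        assert out.transforms["wind"].log

    def test_zero_burned_area_with_unit_offset_maps_to_zero(self):
        idx = pd.period_range("2001-01", periods=2, freq="M")
        ds = TimeSeriesDataset(frame=pd.DataFrame({"area_burned": [0.0, 10.0]}, index=idx))
        out = log_transform(ds)  # default offset +1 for area_burned
        assert out.series("area_burned")[0] == 0.0
        assert out.transforms["area_burned"].log_offset == 1.0

    def test_nonpositive_value_without_offset_lists_months(self):
        idx = pd.period_range("2001-01", periods=3, freq="M")
        ds = TimeSeriesDataset(frame=pd.DataFrame({"wind": [2.0, 0.0, 3.0]}, index=idx))
        with pytest.raises(ValueError, match="2001-02"):
            log_transform(ds, offsets={"wind": 0.0})

    def test_drop_non_fire_season_removes_winter_months(self):
        idx = pd.period_range("2001-01", periods=24, freq="M")
        ds = TimeSeriesDataset(frame=pd.DataFrame({"wind": np.arange(24.0)}, index=idx))
        out = drop_non_fire_season(ds)
        assert out.n_obs == 18
        assert not any(m in (1, 11, 12) for m in out.frame.index.month)


class TestDifference:
    def test_constant_and_linear_series(self):
        np.testing.assert_array_equal(difference(np.full(10, 3.0), 1), np.zeros(9))
        t = np.arange(1.0, 11.0)
        np.testing.assert_array_equal(difference(t, 1), np.ones(9))
        np.testing.assert_array_equal(difference(t, 2), np.zeros(8))

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            difference(np.arange(10.0), 3)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=60))
    def test_second_difference_is_composition_and_cumsum_inverts(self, values):
        x = np.asarray(values)
        np.testing.assert_allclose(
            difference(x, 2), difference(difference(x, 1), 1), atol=1e-9
        )
        d1 = difference(x, 1)
        np.testing.assert_allclose(np.concatenate([[x[0]], x[0] + np.cumsum(d1)]), x, atol=1e-6)
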