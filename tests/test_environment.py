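import numpy as np
import pandas as pd
import pytest
import xarray as xr
from shapely.geometry import Polygon

from fptrack.environment import (
    CoverageError,
    RasterSeries,
    StaticRaster,
    build_covariate_table,
    lagged_difference,
    spectral_index,
    temporal_mean,
    zonal_mean,
)
from fptrack.utilization import UDPolygon


def make_series(values, times, x=None, y=None, variable="ndvi"):
    values = np.asarray(values, dtype=float)
    x = np.arange(values.shape[2], dtype=float) * 1000 + 500 if x is None else x
    y = np.arange(values.shape[1], dtype=float) * 1000 + 500 if y is None else y
    da = xr.DataArray(values, coords={"time": times, "y": y, "x": x}, dims=("time", "y", "x"))
    return RasterSeries(variable, da)


def square(x0, y0, x1, y1):
    return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


DAYS16 = pd.date_range("2020-01-01", periods=6, freq="16D")


class TestSpectralIndex:
    def test_direct_formula(self):
        assert spectral_index(0.5, 0.3) == pytest.approx(0.25)

    def test_equal_bands_zero(self):
        assert spectral_index(0.4, 0.4, kind="mndwi") == pytest.approx(0.0)

    def test_boundary_one(self):
        assert spectral_index(0.7, 0.0) == pytest.approx(1.0)

    def test_both_zero_missing(self):
        assert np.isnan(spectral_index(0.0, 0.0))

    def test_negative_band_rejected(self):
        with pytest.raises(ValueError):
            spectral_index(-0.1, 0.5)

    def test_always_in_unit_interval(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0, 1, 500), rng.uniform(0, 1, 500)
        out = spectral_index(a, b)
        assert np.nanmin(out) >= -1 and np.nanmax(out) <= 1


class TestTemporalMean:
    def test_window_inside_single_composite(self):
        vals = np.arange(6)[:, None, None] * np.ones((6, 2, 2))
        s = make_series(vals, DAYS16, variable="temp")
        out = temporal_mean(s, pd.Timestamp("2020-01-18"), pd.Timestamp("2020-01-30"))
        np.testing.assert_allclose(out.values, 1.0)  # second composite only

    def test_two_slice_average(self):
        vals = np.stack([np.full((2, 2), 0.2), np.full((2, 2), 0.4)])
        s = make_series(vals, DAYS16[:2])
        out = temporal_mean(s, pd.Timestamp("2020-01-10"), pd.Timestamp("2020-01-20"))
        np.testing.assert_allclose(out.values, 0.3)

    def test_matches_daily_expansion_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, (6, 2, 2))
        s = make_series(vals, DAYS16, variable="precip")
        daily = np.repeat(vals, 16, axis=0)  # day-level expansion
        day_index = pd.date_range(DAYS16[0], periods=96, freq="D")
        for _ in range(20):
            i0, i1 = sorted(rng.integers(0, 95, 2))
            t0, t1 = day_index[i0], day_index[i1]
            out = temporal_mean(s, t0, t1)
            # oracle: mean over the composites containing any queried day
            comp = sorted({min(i // 16, 5) for i in range(i0, i1 + 1)})
            np.testing.assert_allclose(out.values, vals[comp].mean(axis=0))

    def test_uncovered_window_names_variable(self):
        s = make_series(np.ones((2, 2, 2)), DAYS16[:2], variable="mndwi")
        with pytest.raises(CoverageError, match="mndwi"):
            temporal_mean(s, pd.Timestamp("2021-06-01"), pd.Timestamp("2021-06-10"))

    def test_reversed_window_rejected(self):
        s = make_series(np.ones((2, 2, 2)), DAYS16[:2])
        with pytest.raises(ValueError):
            temporal_mean(s, pd.Timestamp("2020-02-01"), pd.Timestamp("2020-01-01"))


class TestZonalMean:
    def test_constant_raster(self):
        da = xr.DataArray(np.full((4, 4), 3.7), coords={"y": np.arange(4.0) * 1000 + 500, "x": np.arange(4.0) * 1000 + 500})
        assert zonal_mean(da, square(200, 200, 3500, 3500)) == pytest.approx(3.7)

    def test_two_cell_average(self):
        da = xr.DataArray(np.array([[1.0, 3.0]]), coords={"y": [500.0], "x": [500.0, 1500.0]})
        assert zonal_mean(da, square(0, 0, 2000, 1000)) == pytest.approx(2.0)

    def test_small_polygon_nearest_cell(self):
        da = xr.DataArray(np.array([[1.0, 3.0]]), coords={"y": [500.0], "x": [500.0, 1500.0]})
        tiny = square(1400, 600, 1450, 650)  # contains no cell centre
        assert zonal_mean(da, tiny) == pytest.approx(3.0)

    def test_no_overlap_raises(self):
        da = xr.DataArray(np.ones((2, 2)), coords={"y": [500.0, 1500.0], "x": [500.0, 1500.0]})
        with pytest.raises(CoverageError):
            zonal_mean(da, square(90_000, 90_000, 91_000, 91_000))

    def test_supersampled_oracle(self):
        rng = np.random.default_rng(2)
        ny = nx = 12
        vals = rng.uniform(0, 1, (ny, nx))
        cell = 1000.0
        y = np.arange(ny) * cell + cell / 2
        x = np.arange(nx) * cell + cell / 2
        da = xr.DataArray(vals, coords={"y": y, "x": x})
        poly = Polygon([(1500, 1500), (9500, 2500), (8000, 9000), (2500, 8000)])
        got = zonal_mean(da, poly)
        # oracle: 10x supersampled cell-centre membership
        fine = cell / 10
        fy = np.arange(ny * 10) * fine + fine / 2
        fx = np.arange(nx * 10) * fine + fine / 2
        import shapely

        xx, yy = np.meshgrid(fx, fy)
        inside = shapely.covers(poly, shapely.points(xx.ravel(), yy.ravel()))
        fine_vals = np.repeat(np.repeat(vals, 10, axis=0), 10, axis=1).ravel()[inside]
        assert got == pytest.approx(fine_vals.mean(), abs=0.05)


class TestLaggedDifference:
    def test_time_constant_field_zero(self):
        s = make_series(np.full((6, 2, 2), 0.4), DAYS16)
        d = lagged_difference(s, pd.Timestamp("2020-02-20"), pd.Timestamp("2020-03-01"),
                              pd.Timedelta(days=32), square(0, 0, 2000, 2000))
        assert d == pytest.approx(0.0)

    def test_linear_ramp_gives_rate_times_lag(self):
        # field increases m per day; composites carry the mean of their window
        m = 0.002
        day_means = [(np.arange(16) + 16 * k).mean() * m for k in range(6)]
        vals = np.array(day_means)[:, None, None] * np.ones((6, 2, 2))
        s = make_series(vals, DAYS16)
        for lag in (16, 32):
            d = lagged_difference(s, pd.Timestamp("2020-02-25"), pd.Timestamp("2020-03-05"),
                                  pd.Timedelta(days=lag), square(0, 0, 2000, 2000))
            assert d == pytest.approx(m * lag, abs=m * 16)

    def test_step_increase_recovered(self):
        vals = np.concatenate([np.full((3, 2, 2), 0.1), np.full((3, 2, 2), 0.3)])
        s = make_series(vals, DAYS16)
        d = lagged_difference(s, pd.Timestamp("2020-03-01"), pd.Timestamp("2020-03-10"),
                              pd.Timedelta(days=32), square(0, 0, 2000, 2000))
        assert d == pytest.approx(0.2)

    def test_uncovered_lagged_window_raises(self):
        s = make_series(np.ones((6, 2, 2)) * 0.1, DAYS16)
        with pytest.raises(CoverageError):
            lagged_difference(s, pd.Timestamp("2020-01-05"), pd.Timestamp("2020-01-10"),
                              pd.Timedelta(days=32), square(0, 0, 2000, 2000))

    def test_order_of_averaging_commutes_on_complete_rasters(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 1, (6, 4, 4))
        s = make_series(vals, DAYS16)
        poly = square(200, 200, 3600, 3600)
        t0, t1 = pd.Timestamp("2020-01-20"), pd.Timestamp("2020-02-25")
        spatial_then_temporal = np.mean(
            [zonal_mean(s.data.isel(time=k), poly) for k in range(1, 4)]
        )
        temporal_then_spatial = zonal_mean(temporal_mean(s, t0, t1), poly)
        assert temporal_then_spatial == pytest.approx(spatial_then_temporal)


class TestCovariateTable:
    def _bundle(self, n_time=8):
        times16 = pd.date_range("2020-01-01", periods=n_time, freq="16D")
        days = pd.date_range("2020-01-01", periods=16 * n_time, freq="D")
        grid = dict(x=None, y=None)
        ndvi = make_series(np.full((n_time, 4, 4), 0.3), times16, variable="ndvi")
        mndwi = make_series(np.full((n_time, 4, 4), -0.1), times16, variable="mndwi")
        precip = make_series(np.full((len(days), 4, 4), 1.5), days, variable="precip")
        temp = make_series(np.full((len(days), 4, 4), 21.0), days, variable="temp")
        elev = StaticRaster("elev", xr.DataArray(
            np.full((4, 4), 880.0),
            coords={"y": np.arange(4.0) * 1000 + 500, "x": np.arange(4.0) * 1000 + 500},
        ))
        return ndvi, mndwi, precip, temp, elev

    def _polygon(self, pid, t0, t1):
        return UDPolygon(
            track_label="b1", segment_id=1, polygon_id=pid,
            geometry=square(200, 200, 3500, 3500), area_km2=10.0,
            t_start=pd.Timestamp(t0), t_end=pd.Timestamp(t1),
            n_fixes=10, mfpt_rmax_h=20.0,
        )

    def test_constant_fields_give_levels_and_zero_deltas(self):
        ndvi, mndwi, precip, temp, elev = self._bundle()
        table = build_covariate_table(
            [self._polygon("p0", "2020-03-01", "2020-03-10")],
            ndvi, mndwi, precip, temp, elev, sites={"b1": "BAR"},
        )
        row = table.iloc[0]
        assert row["ndvi_t"] == pytest.approx(0.3)
        assert row["temp"] == pytest.approx(21.0)
        assert row["elev"] == pytest.approx(880.0)
        for c in ("d_ndvi_16", "d_ndvi_32", "d_mndwi_16", "d_mndwi_32", "d_precip_16", "d_precip_32"):
            assert row[c] == pytest.approx(0.0)
        assert row["log_mfpt"] == pytest.approx(np.log(20.0))

    def test_record_per_polygon_with_twelve_predictors(self):
        from fptrack.environment import PREDICTOR_COLUMNS

        ndvi, mndwi, precip, temp, elev = self._bundle()
        polys = [self._polygon(f"p{i}", "2020-03-01", "2020-03-10") for i in range(5)]
        table = build_covariate_table(polys, ndvi, mndwi, precip, temp, elev, sites={"b1": "BAR"})
        assert len(table) == 5
        assert len(PREDICTOR_COLUMNS) == 12
        assert set(PREDICTOR_COLUMNS) <= set(table.columns)

    def test_uncovered_lag_window_drops_record(self):
        ndvi, mndwi, precip, temp, elev = self._bundle()
        polys = [
            self._polygon("early", "2020-01-05", "2020-01-10"),  # 32-day lag precedes series
            self._polygon("ok", "2020-03-01", "2020-03-10"),
        ]
        table = build_covariate_table(polys, ndvi, mndwi, precip, temp, elev, sites={"b1": "BAR"})
        assert table["polygon_id"].tolist() == ["ok"]

    def test_missing_site_mapping_is_error(self):
        ndvi, mndwi, precip, temp, elev = self._bundle()
        with pytest.raises(KeyError, match="b1"):
            build_covariate_table(
                [self._polygon("p0", "2020-03-01", "2020-03-10")],
                ndvi, mndwi, precip, temp, elev, sites={"other": "BAR"},
            )
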