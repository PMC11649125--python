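"""Cleaning-chain behaviour: gap-fill, IQR screen, SG smoothing, MVC,
soil-moisture combination, VPD and resampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from agbpipe import preprocess as prep
from agbpipe.grids import GridGeo, GridStack
from tests.conftest import stack_from

M = np.nan


class TestFillMissingLinear:
    @pytest.mark.parametrize("series, expected", [
        ([1, M, 3], [1, 2, 3]),
        ([M, 5, 5], [5, 5, 5]),
        ([0, M, M, 6], [0, 2, 4, 6]),
        ([1, 2, M], [1, 2, 2]),
    ])
    def test_interpolation_and_edge_extension(self, series, expected):
        s = np.asarray(series, dtype=float)
        filled, mask = prep.fill_missing_linear(s, ~np.isfinite(s))
        assert np.allclose(filled, expected)
        assert not mask.any()

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="unfillable"):
            prep.fill_missing_linear(np.full(5, np.nan), np.ones(5, bool))


class TestIqrScreen:
    def test_hand_computed_fences(self):
        # Q1=3.25, Q3=7.75, IQR=4.5 → upper fence 14.5: only 100 is out
        s = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], dtype=float)
        mask, flags = prep.remove_outliers_iqr(s)
        assert flags.sum() == 1 and flags[-1]

    def test_constant_series_has_no_outliers(self):
        _, flags = prep.remove_outliers_iqr(np.full(8, 2.0))
        assert not flags.any()

    def test_huge_k_keeps_everything(self):
        _, flags = prep.remove_outliers_iqr(np.array([1.0, 2, 3, 4]), k=1000)
        assert not flags.any()

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            prep.remove_outliers_iqr(np.arange(5.0), k=0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            prep.remove_outliers_iqr(np.array([1.0, 2, 3]))

    def test_idempotent_on_cleaned_series(self):
        s = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], dtype=float)
        mask, flags = prep.remove_outliers_iqr(s)
        _, flags2 = prep.remove_outliers_iqr(s, mask)
        assert not flags2.any()


class TestSgFilter:
    def test_reproduces_a_quadratic_exactly(self):
        t = np.arange(11, dtype=float)
        s = 2.0 + 0.5 * t - 0.1 * t ** 2
        assert np.allclose(prep.sg_filter(s, 5, 2), s, atol=1e-9)

    def test_constant_is_unchanged(self):
        assert np.allclose(prep.sg_filter(np.full(9, 3.0)), 3.0)

    def test_interior_point_matches_direct_least_squares(self):
        # centre value of the parabola fitted to the window [1,0,1,0,1]
        s = np.array([0, 1, 0, 1, 0, 1, 0], dtype=float)
        window = s[1:6]
        x = np.arange(-2.0, 3.0)
        coef = np.polynomial.polynomial.polyfit(x, window, 2)
        assert np.isclose(prep.sg_filter(s, 5, 2)[3], coef[0], atol=1e-12)

    @pytest.mark.parametrize("window, order", [(4, 2), (5, 5), (5, 6)])
    def test_bad_parameters_rejected(self, window, order):
        with pytest.raises(ValueError):
            prep.sg_filter(np.arange(10.0), window, order)

    def test_gappy_series_rejected(self):
        with pytest.raises(ValueError, match="gap-free"):
            prep.sg_filter(np.array([1.0, np.nan, 3, 4, 5]))


class TestMvc:
    def test_monthly_max_of_biweekly(self):
        time = pd.DatetimeIndex(["2000-01-05", "2000-01-15", "2000-01-25",
                                 "2000-02-10", "2000-02-20"])
        v = np.array([0.2, 0.6, 0.4, 0.3, 0.5]).reshape(-1, 1, 1)
        st_ = GridStack(v, np.zeros(v.shape, bool), "1", time, GridGeo())
        out = prep.mvc_monthly(st_)
        assert np.allclose(out.values[:, 0, 0], [0.6, 0.5])

    def test_fully_masked_month_stays_masked(self):
        time = pd.DatetimeIndex(["2000-01-05", "2000-01-25", "2000-02-10"])
        v = np.array([0.2, 0.6, 0.4]).reshape(-1, 1, 1)
        mask = np.array([True, True, False]).reshape(-1, 1, 1)
        out = prep.mvc_monthly(GridStack(v, mask, "1", time, GridGeo()))
        assert out.mask[0, 0, 0] and not out.mask[1, 0, 0]

    def test_composite_dominates_observations(self, small_scenario):
        _, inputs, _ = small_scenario
        out = prep.mvc_monthly(inputs.ndvi)
        vals = inputs.ndvi.data_nan()
        key = (inputs.ndvi.time.year * 12 + inputs.ndvi.time.month - 1)
        for i, ym in enumerate(np.unique(key)):
            month_obs = vals[key == ym]
            diff = out.data_nan()[i] - np.nanmax(month_obs, axis=0)
            assert np.nanmin(diff) >= -1e-12


class TestSoilMoisture:
    def test_thickness_weights(self):
        top = stack_from([0.2])
        mid = stack_from([0.4])
        out = prep.combine_soil_moisture(top, mid)
        assert np.isclose(out.values[0, 0, 0], 0.35)

    def test_identical_layers_pass_through(self):
        top = stack_from([0.3, 0.25])
        out = prep.combine_soil_moisture(top, top.copy())
        assert np.allclose(out.data_nan(), top.data_nan())

    def test_mask_propagates(self):
        top = stack_from([np.nan])
        mid = stack_from([0.4])
        assert prep.combine_soil_moisture(top, mid).mask.all()

    def test_misaligned_axes_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            prep.combine_soil_moisture(stack_from([0.1]), stack_from([0.1, 0.2]))


class TestVpd:
    def test_saturated_air_has_zero_deficit(self):
        out = prep.compute_vpd(stack_from([25.0], "degC"), stack_from([100.0], "%"))
        assert np.isclose(out.values[0, 0, 0], 0.0)

    def test_hand_evaluated_tetens(self):
        out = prep.compute_vpd(stack_from([25.0], "degC"), stack_from([50.0], "%"))
        es = 0.6108 * np.exp(17.27 * 25 / 262.3)
        assert np.isclose(out.values[0, 0, 0], es * 0.5, rtol=1e-9)
        assert np.isclose(out.values[0, 0, 0], 1.584, atol=5e-4)

    def test_deficit_increases_with_temperature(self):
        t = stack_from(np.linspace(0, 35, 8), "degC")
        rh = stack_from(np.full(8, 60.0), "%")
        vpd = prep.compute_vpd(t, rh).values[:, 0, 0]
        assert np.all(np.diff(vpd) > 0)

    def test_out_of_range_humidity_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 100\\]"):
            prep.compute_vpd(stack_from([20.0], "degC"), stack_from([120.0], "%"))


class TestResample:
    def test_identity_grid_returns_input(self, monthly_stack):
        out = prep.resample_grid(monthly_stack, monthly_stack.geo,
                                 monthly_stack.grid_shape, "bilinear")
        assert np.allclose(out.data_nan(), monthly_stack.data_nan())

    @pytest.mark.parametrize("method", ["nearest", "bilinear"])
    def test_constant_field_stays_constant(self, method):
        v = np.full((1, 4, 4), 7.0)
        src = GridStack(v, np.zeros(v.shape, bool), "1",
                        pd.DatetimeIndex(["2000-01-15"]), GridGeo())
        tgt = GridGeo(lon0=80.012, lat0=44.988, dlon=0.037, dlat=-0.037)
        out = prep.resample_grid(src, tgt, (3, 3), method)
        assert np.allclose(out.data_nan(), 7.0)

    def test_bilinear_midpoint(self):
        v = np.array([[[0.0, 1.0], [0.0, 1.0]]])
        src = GridStack(v, np.zeros(v.shape, bool), "1",
                        pd.DatetimeIndex(["2000-01-15"]), GridGeo())
        mid = GridGeo(lon0=80.025, lat0=44.975, dlon=0.05, dlat=-0.05)
        out = prep.resample_grid(src, mid, (1, 1), "bilinear")
        assert np.isclose(out.values[0, 0, 0], 0.5)

    def test_disjoint_extent_rejected(self, monthly_stack):
        far = GridGeo(lon0=150.0, lat0=-10.0)
        with pytest.raises(ValueError, match="disjoint"):
            prep.resample_grid(monthly_stack, far, (3, 3))


class TestIdwStations:
    def test_exact_at_station_locations(self):
        geo = GridGeo(lon0=80.0, lat0=45.0)
        df = pd.DataFrame({
            "station_id": ["a", "b"], "lat": [45.0, 44.9], "lon": [80.0, 80.1],
            "date": [pd.Timestamp("2000-01-01")] * 2, "T": [1.0, 5.0]})
        out = prep.idw_station_grid(df, "T", geo, (3, 3))
        assert np.isclose(out.values[0, 0, 0], 1.0)  # pixel centred on station a
        assert np.isclose(out.values[0, 2, 2], 5.0)

    def test_interpolates_between_stations(self):
        geo = GridGeo(lon0=80.0, lat0=45.0)
        df = pd.DataFrame({
            "station_id": ["a", "b"], "lat": [45.0, 45.0], "lon": [80.0, 80.1],
            "date": [pd.Timestamp("2000-01-01")] * 2, "T": [0.0, 10.0]})
        out = prep.idw_station_grid(df, "T", geo, (1, 3))
        assert np.isclose(out.values[0, 0, 1], 5.0)  # equidistant midpoint


class TestCleaningChain:
    def test_injected_spikes_are_flagged(self, small_scenario):
        _, inputs, truth = small_scenario
        _, _, report = prep.clean_ndvi_stack(inputs.ndvi)
        inj = truth.outlier_positions
        recall = (report.outlier_flags & inj).sum() / inj.sum()
        assert recall >= 0.95

    def test_chain_is_idempotent_on_clean_data(self, small_scenario):
        """Re-cleaning an already clean record fills nothing, flags nothing,
        and only re-smooths: the composite moves well under the noise level."""
        cfg, inputs, _ = small_scenario
        clean1, monthly1, _ = prep.clean_ndvi_stack(inputs.ndvi)
        _, monthly2, rep2 = prep.clean_ndvi_stack(clean1)
        assert rep2.n_filled == 0
        assert rep2.n_outliers_removed == 0
        diff = np.abs(monthly1.data_nan() - monthly2.data_nan())
        assert np.nanmean(diff) < cfg.noise("NDVI") / 4
        assert np.nanmax(diff) < 2 * cfg.noise("NDVI")

    def test_report_accounting(self, small_scenario, tmp_path):
        _, inputs, _ = small_scenario
        _, _, report = prep.clean_ndvi_stack(inputs.ndvi)
        assert report.n_filled == int(inputs.ndvi.mask.sum())
        assert report.n_filled + report.n_outliers_removed <= inputs.ndvi.values.size
        report.to_json(tmp_path / "rep.json")
        assert (tmp_path / "rep.json").exists()


@settings(deadline=None, max_examples=30)
@given(st.lists(st.floats(-100, 100), min_size=4, max_size=50), st.floats(0.5, 5))
def test_iqr_fences_contain_the_quartile_box(values, k):
    s = np.asarray(values)
    _, flags = prep.remove_outliers_iqr(s, k=k)
    q1, q3 = np.quantile(s, [0.25, 0.75])
    inside = (s >= q1) & (s <= q3)
    assert not (flags & inside).any()
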