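"""Light-use-efficiency sub-models against hand-evaluated values and bounds."""

import numpy as np
import pandas as pd
import pytest

from agbpipe import casa
from agbpipe.grids import GridGeo, GridStack, TypeMap
from tests.conftest import stack_from


@pytest.fixture()
def ramp_params():
    """Single-type parameter set with the documented example ramp."""
    return casa.CasaParams({1: casa.TypeCasa(
        eps_max=0.542, ndvi_min=0.05, ndvi_max=0.75,
        fpar_min=0.001, fpar_max=0.95)})


@pytest.fixture()
def one_type_map():
    return TypeMap(np.ones((1, 1), dtype=np.uint8))


class TestFpar:
    @pytest.mark.parametrize("ndvi, expected", [
        (0.05, 0.001),                      # ramp lower anchor
        (0.75, 0.95),                       # ramp upper anchor
        (0.40, 0.001 + (0.35 / 0.70) * 0.949),  # hand evaluation: 0.4755
        (0.01, 0.001),                      # clipped below
        (0.90, 0.95),                       # clipped above
    ])
    def test_ramp(self, ramp_params, one_type_map, ndvi, expected):
        out = casa.compute_fpar(stack_from([ndvi]), ramp_params, one_type_map)
        assert np.isclose(out.values[0, 0, 0], expected, atol=1e-12)

    def test_unknown_type_rejected(self, ramp_params):
        tm = TypeMap(np.full((1, 1), 9, dtype=np.uint8))
        with pytest.raises(KeyError, match="9"):
            casa.compute_fpar(stack_from([0.4]), ramp_params, tm)

    def test_invalid_parameter_table(self):
        with pytest.raises(ValueError):
            casa.TypeCasa(0.542, 0.6, 0.5, 0.001, 0.95)
        with pytest.raises(ValueError):
            casa.TypeCasa(0.542, 0.05, 0.75, 0.001, 0.99)


class TestApar:
    def test_hand_value(self):
        out = casa.compute_apar(stack_from([100.0], "MJ/m2"), stack_from([0.5]))
        assert np.isclose(out.values[0, 0, 0], 25.0)

    def test_zero_fpar_gives_zero(self):
        out = casa.compute_apar(stack_from([500.0], "MJ/m2"), stack_from([0.0]))
        assert out.values[0, 0, 0] == 0.0

    def test_linear_in_radiation(self):
        f = stack_from([0.3])
        a1 = casa.compute_apar(stack_from([200.0], "MJ/m2"), f).values
        a2 = casa.compute_apar(stack_from([400.0], "MJ/m2"), f).values
        assert np.allclose(2 * a1, a2)

    def test_negative_radiation_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            casa.compute_apar(stack_from([-1.0], "MJ/m2"), stack_from([0.5]))


class TestTemperatureStress:
    def test_optimum_twenty_gives_unit_te1(self):
        te1, _ = casa.temperature_stress(stack_from([20.0], "degC"),
                                         np.array([[20.0]]))
        assert np.isclose(te1.values[0, 0, 0], 1.0)

    def test_deep_frost_zeroes_te1(self):
        te1, _ = casa.temperature_stress(stack_from([-15.0], "degC"),
                                         np.array([[20.0]]))
        assert te1.values[0, 0, 0] == 0.0

    def test_te2_at_optimum(self):
        _, te2 = casa.temperature_stress(stack_from([20.0], "degC"),
                                         np.array([[20.0]]))
        expected = 1.1814 / ((1 + np.exp(-2.0)) * (1 + np.exp(-3.0)))
        assert np.isclose(te2.values[0, 0, 0], expected, atol=1e-12)
        assert np.isclose(te2.values[0, 0, 0], 0.9912, atol=5e-5)

    def test_te2_peaks_near_optimum(self):
        # the double logistic is mildly asymmetric (0.2 vs 0.3 rates), so the
        # peak sits within a couple of degrees of the optimum, not exactly on it
        t = stack_from(np.linspace(-20, 40, 61), "degC")
        _, te2 = casa.temperature_stress(t, np.array([[15.0]]))
        peak_t = t.values[te2.values[:, 0, 0].argmax(), 0, 0]
        assert abs(peak_t - 15.0) <= 2.0


class TestWaterStress:
    def test_no_limitation_when_supply_meets_demand(self):
        w = casa.water_stress(ppt=stack_from([60.0], "mm"),
                              pet=stack_from([60.0], "mm"))
        assert np.isclose(w.values[0, 0, 0], 1.0)

    def test_dry_limit(self):
        w = casa.water_stress(ppt=stack_from([0.0], "mm"),
                              pet=stack_from([50.0], "mm"))
        assert np.isclose(w.values[0, 0, 0], 0.5)

    def test_hand_value(self):
        w = casa.water_stress(ppt=stack_from([30.0], "mm"),
                              pet=stack_from([60.0], "mm"))
        assert np.isclose(w.values[0, 0, 0], 0.75)

    def test_soil_moisture_mode(self):
        w = casa.water_stress(sm_ratio=stack_from([0.6]))
        assert np.isclose(w.values[0, 0, 0], 0.8)

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError, match="supply"):
            casa.water_stress()


class TestNpp:
    def test_hand_product(self):
        field = casa.compute_npp(stack_from([25.0], "MJ/m2"),
                                 stack_from([1.0]), stack_from([0.9912]),
                                 stack_from([0.75]), 0.542)
        assert np.isclose(field.npp.values[0, 0, 0],
                          25 * 1.0 * 0.9912 * 0.75 * 0.542, atol=1e-12)
        assert np.isclose(field.npp.values[0, 0, 0], 10.073, atol=5e-4)

    def test_zero_stress_zeroes_npp(self):
        field = casa.compute_npp(stack_from([25.0], "MJ/m2"),
                                 stack_from([0.0]), stack_from([0.99]),
                                 stack_from([0.75]), 0.542)
        assert field.npp.values[0, 0, 0] == 0.0

    def test_monotone_in_each_factor(self):
        base = dict(apar=10.0, t1=0.8, t2=0.9, w=0.7)
        def npp(**kw):
            a = {**base, **kw}
            f = casa.compute_npp(stack_from([a["apar"]], "MJ/m2"),
                                 stack_from([a["t1"]]), stack_from([a["t2"]]),
                                 stack_from([a["w"]]), 0.542)
            return f.npp.values[0, 0, 0]
        ref = npp()
        for key in base:
            assert npp(**{key: base[key] * 1.1}) >= ref

    def test_bounds_on_random_inputs(self):
        """FPAR, Wε and NPP respect their bounds on a large random sample."""
        rng = np.random.default_rng(0)
        n = 10 ** 6
        time = pd.DatetimeIndex(["2000-01-15"])
        geo = GridGeo()
        shape = (1, 1000, 1000)
        ndvi = GridStack(rng.uniform(-0.2, 1.0, shape),
                         np.zeros(shape, bool), "1", time, geo)
        params = casa.CasaParams.default()
        tm = TypeMap(np.ones(shape[1:], dtype=np.uint8))
        fpar = casa.compute_fpar(ndvi, params, tm)
        p = params[1]
        assert np.nanmin(fpar.values) >= p.fpar_min - 1e-12
        assert np.nanmax(fpar.values) <= p.fpar_max + 1e-12
        ppt = GridStack(rng.uniform(0, 200, shape), np.zeros(shape, bool),
                        "mm", time, geo)
        pet = GridStack(rng.uniform(1e-3, 200, shape), np.zeros(shape, bool),
                        "mm", time, geo)
        w = casa.water_stress(ppt=ppt, pet=pet)
        assert np.nanmin(w.values) >= 0.5 and np.nanmax(w.values) <= 1.0
        sol = GridStack(rng.uniform(0, 800, shape), np.zeros(shape, bool),
                        "MJ/m2", time, geo)
        apar = casa.compute_apar(sol, fpar)
        t = GridStack(rng.uniform(-30, 40, shape), np.zeros(shape, bool),
                      "degC", time, geo)
        te1, te2 = casa.temperature_stress(t, rng.uniform(0, 30, shape[1:]))
        field = casa.compute_npp(apar, te1, te2, w, 0.542, fpar=fpar)
        assert np.nanmin(field.npp.values) >= 0.0
        assert np.nanmin(te1.values) >= 0.0 and np.nanmax(te1.values) <= 1.2
        assert np.nanmin(te2.values) >= 0.0 and np.nanmax(te2.values) <= 1.2
        assert n == shape[1] * shape[2]


class TestTruthRecovery:
    def test_pipeline_reproduces_generated_npp(self, small_scenario):
        """Preprocessing + forward model recover the truth NPP within the
        generator's noise bound."""
        from agbpipe import preprocess as prep
        _, inputs, truth = small_scenario
        _, monthly, _ = prep.clean_ndvi_stack(inputs.ndvi)
        params = casa.CasaParams.default()
        fpar = casa.compute_fpar(monthly, params, inputs.type_map)
        apar = casa.compute_apar(inputs.sr, fpar)
        topt = casa.compute_topt(monthly, inputs.t)
        te1, te2 = casa.temperature_stress(inputs.t, topt)
        w = casa.water_stress(ppt=inputs.ppt, pet=casa.hamon_pet(inputs.t))
        eps = casa.eps_max_field(inputs.type_map, params)
        npp = casa.compute_npp(apar, te1, te2, w, eps).npp
        rmse = float(np.sqrt(np.nanmean(
            (npp.data_nan() - truth.npp_true.data_nan()) ** 2)))
        assert rmse <= truth.npp_rmse_bound


class TestAggregate:
    @pytest.fixture()
    def two_year_monthly(self):
        time = pd.DatetimeIndex([pd.Timestamp(2000 + y, m, 15)
                                 for y in range(2) for m in range(1, 13)])
        vals = np.full((24, 1, 1), 10.0)
        return GridStack(vals, np.zeros(vals.shape, bool), "gC/m2", time,
                         GridGeo())

    def test_annual_sum(self, two_year_monthly):
        out = casa.aggregate(two_year_monthly, "annual", "sum")
        assert np.allclose(out.values, 120.0)

    def test_spring_is_march_to_may(self):
        time = pd.DatetimeIndex([pd.Timestamp(2000, m, 15) for m in range(1, 13)])
        vals = np.arange(1.0, 13.0).reshape(-1, 1, 1)  # value = month number
        st_ = GridStack(vals, np.zeros(vals.shape, bool), "gC/m2", time, GridGeo())
        out = casa.aggregate(st_, "spring", "sum")
        assert np.isclose(out.values[0, 0, 0], 3 + 4 + 5)

    def test_seasons_partition_the_year(self, two_year_monthly):
        """Four seasonal sums equal the annual sum under the cross-year
        winter convention (winter of y spans Dec y−1 … Feb y)."""
        st_ = two_year_monthly
        annual_y1 = casa.aggregate(st_, "annual", "sum").values[1, 0, 0]
        parts = 0.0
        for season in ("spring", "summer", "autumn", "winter"):
            agg = casa.aggregate(st_, season, "sum", on_incomplete="skip")
            sel = agg.time.year == 2001
            parts += float(agg.values[sel, 0, 0][0])
        # winter 2001 = Dec 2000 + Jan/Feb 2001: a different partition of the
        # 24-month record, but the same total per complete year
        assert np.isclose(parts, annual_y1)

    def test_missing_months_listed(self):
        time = pd.DatetimeIndex([pd.Timestamp(2000, m, 15) for m in range(1, 12)])
        vals = np.zeros((11, 1, 1))
        st_ = GridStack(vals, np.zeros(vals.shape, bool), "gC/m2", time, GridGeo())
        with pytest.raises(ValueError, match="12"):
            casa.aggregate(st_, "annual", "sum")

    def test_winter_skips_incomplete_years(self, two_year_monthly):
        out = casa.aggregate(two_year_monthly, "winter", "sum",
                             on_incomplete="skip")
        assert list(out.time.year) == [2001]


def test_topt_is_temperature_of_peak_ndvi_month():
    time = pd.DatetimeIndex([pd.Timestamp(2000, m, 15) for m in range(1, 13)])
    ndvi = np.zeros((12, 1, 1)); ndvi[6] = 0.9     # peak in July
    t = np.arange(12, dtype=float).reshape(-1, 1, 1) * 2.0
    g = GridGeo()
    topt = casa.compute_topt(
        GridStack(ndvi, np.zeros(ndvi.shape, bool), "1", time, g),
        GridStack(t, np.zeros(t.shape, bool), "degC", time, g))
    assert np.isclose(topt[0, 0], 12.0)  # July temperature


def test_hamon_pet_positive_and_increasing_with_temperature():
    pet_cold = casa.hamon_pet(stack_from([0.0], "degC"))
    pet_warm = casa.hamon_pet(stack_from([25.0], "degC"))
    assert pet_warm.values[0, 0, 0] > pet_cold.values[0, 0, 0] > 0
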