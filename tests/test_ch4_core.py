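"""CH4 core: substrate supply, production limiters, pathways, mass balance."""

import numpy as np
import pandas as pd
import pytest

from wetlandch4 import ch4_core as ch
from wetlandch4.params import CH4_DEFAULTS, ch4_params

Q10 = CH4_DEFAULTS["q10"]


def _state(**kw):
    defaults = dict(litter_pool=0.0, labile_som_pool=0.0, eh=-250.0,
                    dissolved_ch4=0.0)
    defaults.update(kw)
    return ch.MethaneState(**defaults)


class TestSoilTemperature:
    def test_constant_history_is_fixed_point(self):
        assert ch.soil_temperature([20.0] * 10) == 20.0

    def test_trailing_mean(self):
        assert ch.soil_temperature([0.0, 5.0, 10.0, 15.0, 20.0]) == 10.0

    def test_frozen_clamp(self):
        assert ch.soil_temperature([-10.0] * 7) == 0.0

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            ch.soil_temperature([])


class TestRedox:
    def test_floor_under_flooding(self):
        s = _state(eh=-250.0)
        assert ch.update_eh(s, wt=5.0) == -250.0

    def test_one_flooded_step(self):
        s = _state(eh=-100.0)
        assert ch.update_eh(s, wt=0.0) == -120.0

    def test_drained_recovery_bounded(self):
        s = _state(eh=-250.0)
        for _ in range(400):
            s.eh = ch.update_eh(s, wt=-10.0)
        assert s.eh == CH4_DEFAULTS["eh_max"]


class TestSubstrate:
    def test_no_substrate_without_inputs(self, carex_traits):
        s = _state()
        total = ch.substrate_supply(carex_traits, 0.0,
                                    pd.Timestamp("2001-07-01"), s, 20.0)
        assert total == 0.0

    def test_exudates_linear_in_anpp(self, carex_traits):
        day = pd.Timestamp("2001-07-01")
        a = ch.substrate_supply(carex_traits, 480.0, day, _state(), 20.0)
        b = ch.substrate_supply(carex_traits, 960.0, day, _state(), 20.0)
        assert b == pytest.approx(2.0 * a)

    def test_litter_q10_ratio(self, carex_traits):
        day = pd.Timestamp("2001-02-01")  # off-season: no exudates
        warm = ch.substrate_supply(carex_traits, 0.0, day,
                                   _state(litter_pool=100.0), 30.0)
        cool = ch.substrate_supply(carex_traits, 0.0, day,
                                   _state(litter_pool=100.0), 20.0)
        assert warm / cool == pytest.approx(Q10)

    def test_pools_conserved(self, carex_traits):
        s = _state(litter_pool=100.0, labile_som_pool=50.0)
        total = ch.substrate_supply(carex_traits, 0.0,
                                    pd.Timestamp("2001-02-01"), s, 25.0)
        assert s.litter_pool + s.labile_som_pool + total == pytest.approx(150.0)

    def test_seasonal_allocation_normalised(self):
        days = pd.date_range("2001-01-01", "2001-12-31", freq="D")
        total = sum(ch.growth_allocation(d) for d in days)
        assert total == pytest.approx(1.0)


class TestProduction:
    def test_redox_cutoff(self, soil):
        assert ch.production_rate(10.0, 30.0, -100.0, soil) == 0.0

    def test_redox_ramp_midpoint(self, soil):
        full = ch.production_rate(10.0, 30.0, -150.0, soil)
        half = ch.production_rate(10.0, 30.0, -125.0, soil)
        assert half == pytest.approx(0.5 * full)

    def test_q10_scaling_exact(self, soil):
        p30 = ch.production_rate(10.0, 30.0, -250.0, soil)
        p20 = ch.production_rate(10.0, 20.0, -250.0, soil)
        assert p30 / p20 == pytest.approx(Q10)

    def test_texture_index_increases_with_sand(self):
        fine = ch.texture_index(ch.SoilProfile(5.0, 150.0, 0.6))
        coarse = ch.texture_index(ch.SoilProfile(60.0, 150.0, 0.6))
        assert coarse > fine


class TestPartition:
    def test_nothing_from_empty_store(self, carex_traits):
        s = _state()
        emission, oxidized, _ = ch.partition_and_oxidize(
            0.0, s, 5.0, carex_traits, g_norm=1.0)
        assert emission == 0.0 and oxidized == 0.0

    def test_ebullition_exports_excess_when_flooded(self, carex_traits):
        c_sat = CH4_DEFAULTS["c_sat"]
        s = _state(dissolved_ch4=c_sat + 2.0)
        _, _, paths = ch.partition_and_oxidize(
            0.0, s, 5.0, carex_traits, g_norm=0.0)
        assert paths["ebullition"] == pytest.approx(2.0)
        assert s.dissolved_ch4 <= c_sat

    def test_no_ebullition_when_drained(self, carex_traits):
        s = _state(dissolved_ch4=CH4_DEFAULTS["c_sat"] + 2.0)
        _, _, paths = ch.partition_and_oxidize(
            0.0, s, -5.0, carex_traits, g_norm=0.0)
        assert paths["ebullition"] == 0.0

    def test_single_step_mass_balance(self, carex_traits):
        s = _state(dissolved_ch4=1.0)
        before = s.dissolved_ch4
        prod_c = 0.7
        emission, oxidized, _ = ch.partition_and_oxidize(
            prod_c, s, 3.0, carex_traits, g_norm=0.8)
        prod_mass = prod_c * 16.0 / 12.0
        assert emission + oxidized + (s.dissolved_ch4 - before) == \
            pytest.approx(prod_mass, abs=1e-12)


class TestSimulation:
    @pytest.fixture
    def anpp(self):
        return {2001: 480.0, 2002: 480.0}

    def test_century_scale_mass_balance(self, baseline_climate_2y, carex_wt,
                                        soil, carex_traits, anpp):
        res = ch.simulate_ch4_daily(baseline_climate_2y, carex_wt, anpp,
                                    soil, carex_traits)
        drift = (res["production"].sum() - res["flux"].sum()
                 - res["oxidized"].sum() - res["store"].iloc[-1])
        assert abs(drift) <= 1e-9
        assert (res["flux"] >= 0).all()
        assert (res["store"] >= 0).all()

    def test_permanently_drained_emits_nothing(self, baseline_climate_2y,
                                               carex_wt, soil, carex_traits,
                                               anpp):
        dry = carex_wt.copy()
        dry["wt"] = -50.0
        res = ch.simulate_ch4_daily(baseline_climate_2y, dry, anpp, soil,
                                    carex_traits)
        assert ch.annual_flux(res, 2001) == 0.0
        assert ch.annual_flux(res, 2002) == 0.0

    def test_flooded_exceeds_drained(self, baseline_climate_2y, carex_wt,
                                     soil, carex_traits, anpp):
        wet = carex_wt.copy()
        wet["wt"] = 10.0
        dry = carex_wt.copy()
        dry["wt"] = -50.0
        flooded = ch.simulate_ch4_daily(baseline_climate_2y, wet, anpp, soil,
                                        carex_traits)
        drained = ch.simulate_ch4_daily(baseline_climate_2y, dry, anpp, soil,
                                        carex_traits)
        assert ch.annual_flux(flooded, 2001) >= ch.annual_flux(drained, 2001)

    def test_standing_depth_insensitivity(self, baseline_climate_2y, carex_wt,
                                          soil, carex_traits, anpp):
        shallow = carex_wt.copy()
        shallow["wt"] = 5.0
        deep = carex_wt.copy()
        deep["wt"] = 15.0
        a = ch.simulate_ch4_daily(baseline_climate_2y, shallow, anpp, soil,
                                  carex_traits)
        b = ch.simulate_ch4_daily(baseline_climate_2y, deep, anpp, soil,
                                  carex_traits)
        np.testing.assert_allclose(a["flux"], b["flux"])

    def test_flux_nondecreasing_in_anpp(self, baseline_climate_2y, carex_wt,
                                        soil, carex_traits, anpp):
        low = ch.simulate_ch4_daily(baseline_climate_2y, carex_wt, anpp,
                                    soil, carex_traits)
        high = ch.simulate_ch4_daily(baseline_climate_2y, carex_wt,
                                     {y: 2 * v for y, v in anpp.items()},
                                     soil, carex_traits)
        assert ch.annual_flux(high, 2001) >= ch.annual_flux(low, 2001)

    def test_baseline_flooded_magnitude(self, baseline_climate_2y, carex_wt,
                                        soil, carex_traits, anpp):
        wet = carex_wt.copy()
        wet["wt"] = 10.0
        res = ch.simulate_ch4_daily(baseline_climate_2y, wet, anpp, soil,
                                    carex_traits)
        flux = ch.annual_flux(res, 2002)
        assert 10.0 <= flux <= 500.0

    def test_deterministic(self, baseline_climate_2y, carex_wt, soil,
                           carex_traits, anpp):
        a = ch.simulate_ch4_daily(baseline_climate_2y, carex_wt, anpp, soil,
                                  carex_traits)
        b = ch.simulate_ch4_daily(baseline_climate_2y, carex_wt, anpp, soil,
                                  carex_traits)
        pd.testing.assert_frame_equal(a, b)

    def test_misaligned_series_rejected(self, baseline_climate_2y, carex_wt,
                                        soil, carex_traits, anpp):
        with pytest.raises(ValueError, match="misaligned"):
            ch.simulate_ch4_daily(baseline_climate_2y, carex_wt.iloc[:-5],
                                  anpp, soil, carex_traits)

    def test_missing_anpp_year_rejected(self, baseline_climate_2y, carex_wt,
                                        soil, carex_traits):
        with pytest.raises(ValueError, match="ANPP"):
            ch.simulate_ch4_daily(baseline_climate_2y, carex_wt,
                                  {2001: 480.0}, soil, carex_traits)


class TestAnnualFlux:
    def test_arithmetic(self):
        dates = pd.date_range("2001-01-01", "2001-12-31", freq="D")
        series = pd.DataFrame({"date": dates, "flux": 0.1})
        assert ch.annual_flux(series, 2001) == pytest.approx(36.5)

    def test_partition_over_years(self, baseline_climate_2y, carex_wt, soil,
                                  carex_traits):
        anpp = {2001: 480.0, 2002: 480.0}
        res = ch.simulate_ch4_daily(baseline_climate_2y, carex_wt, anpp,
                                    soil, carex_traits)
        per_year = ch.annual_flux_series(res)
        assert per_year.sum() == pytest.approx(res["flux"].sum())

    def test_absent_year_rejected(self):
        series = pd.DataFrame({
            "date": pd.date_range("2001-01-01", periods=10), "flux": 0.0})
        with pytest.raises(ValueError, match="2005"):
            ch.annual_flux(series, 2005)


class TestParamsFile:
    def test_override_and_typo_guard(self):
        p = ch4_params(q10=2.5)
        assert p["q10"] == 2.5 and CH4_DEFAULTS["q10"] == 3.0
        with pytest.raises(KeyError):
            ch4_params(q_ten=2.5)

    def test_unknown_vegetation_rejected(self):
        with pytest.raises(ValueError, match="unknown vegetation"):
            ch.vegetation_traits("sphagnum")
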