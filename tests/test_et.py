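import math

import numpy as np
import pytest

from cropwater.et import (
    CropState,
    SoilEvapState,
    WeatherRecord,
    adjust_kcb_climate,
    cumulate_et,
    daily_etc,
    exposed_wetted_fraction,
    fraction_cover,
    kc_max,
    kr_two_stage,
    ks_from_cwsi,
    penman_monteith_et0,
    run_season,
    scale_kcb_lai,
    soil_evap_coefficient,
)
from oracles import et_chain_oracle


def make_weather(**kw):
    base = dict(date="2023-04-01", T=16.9, u2=2.078, RH_min=40.0,
                Rn=14.33, G=1.05, es=1.997, ea=1.409, Delta=0.122, gamma=0.0666)
    base.update(kw)
    return WeatherRecord(**base)


class TestReferenceET:
    def test_zero_when_no_energy_and_no_vpd(self):
        w = make_weather(Rn=5.0, G=5.0, es=1.5, ea=1.5)
        assert penman_monteith_et0(w) == 0.0

    def test_fao_worked_day(self):
        # frozen from the straight-line oracle on this day's inputs
        w = make_weather()
        expected = et_chain_oracle(
            16.9, 2.078, 40.0, 14.33, 1.05, 1.997, 1.409, 0.122, 0.0666,
            1.15, 0.6, 0.6, 3.0, 0.7, 0.15, 0.0, 0.0, 8.0, 22.0, 1.0,
        )[0]
        assert penman_monteith_et0(w) == pytest.approx(expected, abs=1e-6)
        assert 3.5 < penman_monteith_et0(w) < 4.2  # plausible spring magnitude

    def test_aerodynamic_term_is_linear_in_vpd(self):
        w1 = make_weather(Rn=2.0, G=2.0, es=2.0, ea=1.5)
        w2 = make_weather(Rn=2.0, G=2.0, es=2.5, ea=1.5)
        assert penman_monteith_et0(w2) == pytest.approx(2.0 * penman_monteith_et0(w1), rel=1e-12)

    def test_vapor_pressure_ordering_enforced(self):
        with pytest.raises(ValueError, match="es >= ea"):
            make_weather(es=1.0, ea=1.5)


class TestBasalCoefficient:
    def test_neutral_climate_leaves_kcb(self):
        assert adjust_kcb_climate(1.15, 0.76, u2=2.0, RH_min=45.0) == pytest.approx(1.15)

    def test_sparse_canopy_skips_adjustment(self):
        # below the 0.45 floor the climatic correction is not applied
        assert adjust_kcb_climate(0.25, 0.5, u2=5.0, RH_min=20.0) == 0.25

    def test_windy_dry_day_hand_value(self):
        got = adjust_kcb_climate(1.15, 0.76, u2=3.0, RH_min=40.0)
        expected = 1.15 + (0.76 / 3.0) ** 0.3 * (0.04 * 1.0 - 0.004 * (-5.0))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_lai_scaling_limits(self):
        assert scale_kcb_lai(1.15, 0.0) == pytest.approx(0.15)
        assert scale_kcb_lai(1.15, 50.0) == pytest.approx(1.15, abs=1e-10)

    def test_lai_scaling_hand_value(self):
        got = scale_kcb_lai(1.15, 5.27, k=0.7)
        assert got == pytest.approx(0.15 + 1.0 * (1.0 - math.exp(-0.7 * 5.27)), abs=1e-12)

    def test_lai_scaling_monotone_increasing(self):
        vals = [scale_kcb_lai(1.15, lai) for lai in np.linspace(0, 8, 30)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_rejects_kcb_below_floor(self):
        with pytest.raises(ValueError):
            scale_kcb_lai(0.10, 2.0, Kc_min=0.15)


class TestStressAndSoil:
    @pytest.mark.parametrize("cwsi,expected", [(0.0, 1.0), (1.0, 0.0), (0.25, 0.75)])
    def test_ks_anchors(self, cwsi, expected):
        assert ks_from_cwsi(cwsi) == expected

    def test_ks_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ks_from_cwsi(1.2)

    def test_kc_max_neutral_climate(self):
        assert kc_max(1.15, 1.15, u2=2.0, RH_min=45.0, h_max=0.9) == pytest.approx(1.20)

    def test_kc_max_structure(self):
        # tiny basal coefficient: the climate-adjusted tabular term dominates
        assert kc_max(1.15, 0.05, 2.0, 45.0, 0.9) == pytest.approx(1.15)
        got = kc_max(1.15, 1.2, u2=3.0, RH_min=40.0, h_max=0.96)
        expected = max(1.15 + (0.04 + 0.02) * (0.96 / 3.0) ** 0.3, 1.25)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_fraction_cover_anchors(self):
        assert fraction_cover(0.15, 0.15, 1.2, h=0.5) == 0.0
        assert fraction_cover(1.2, 0.15, 1.2, h=0.7) == 0.99  # clipped
        assert fraction_cover(0.675, 0.15, 1.2, h=0.0) == pytest.approx(0.5)

    def test_exposed_wetted_fraction(self):
        assert exposed_wetted_fraction(0.8, 1.0) == pytest.approx(0.2)
        assert exposed_wetted_fraction(0.0, 0.3) == 0.3
        assert exposed_wetted_fraction(0.99, 1.0) == pytest.approx(0.01)

    def test_kr_two_stages(self):
        assert kr_two_stage(0.0, 8.0, 22.0) == 1.0
        assert kr_two_stage(22.0, 8.0, 22.0) == 0.0
        assert kr_two_stage(15.0, 8.0, 22.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            kr_two_stage(5.0, 10.0, 10.0)

    def test_ke_cap(self):
        assert soil_evap_coefficient(1.0, 1.2, 1.2, 1.0) == 0.0
        assert soil_evap_coefficient(1.0, 1.2, 0.3, 1.0) == pytest.approx(0.9)
        assert soil_evap_coefficient(1.0, 1.2, 0.3, 0.1) == pytest.approx(0.12)


class TestDailyChain:
    def make_crop(self, **kw):
        base = dict(stage="heading", Kcb_tab=1.15, h=0.76, h_max=0.91, LAI=5.27, CWSI=0.2)
        base.update(kw)
        return CropState(**base)

    def test_three_day_chain_matches_oracle(self):
        """The full daily chain agrees with the straight-line transcription."""
        days = [
            make_weather(date="d1", T=12.0, u2=1.2, RH_min=55.0, Rn=10.0, G=1.0,
                         es=1.6, ea=1.1, Delta=float("nan"), gamma=float("nan")),
            make_weather(date="d2", T=18.0, u2=3.5, RH_min=30.0, Rn=15.0, G=1.5,
                         es=2.2, ea=1.2, Delta=float("nan"), gamma=float("nan")),
            make_weather(date="d3", T=25.0, u2=0.8, RH_min=70.0, Rn=13.0, G=1.3,
                         es=3.1, ea=2.6, Delta=float("nan"), gamma=float("nan")),
        ]
        crop = self.make_crop()
        soil = SoilEvapState(REW=8.0, TEW=22.0, fw=1.0)
        de = soil.De
        for w in days:
            comp = daily_etc(w, crop, soil)
            oracle = et_chain_oracle(
                w.T, w.u2, w.RH_min, w.Rn, w.G, w.es, w.ea, w.Delta, w.gamma,
                crop.Kcb_tab, crop.h, crop.h_max, crop.LAI, crop.k, crop.Kc_min,
                crop.CWSI, de, soil.REW, soil.TEW, soil.fw,
            )
            names = ("ET0", "Kcb_adjust", "Kcb_a", "Ks", "Kc_max", "fc", "few", "Kr", "Ke", "ETc")
            for name, want in zip(names, oracle[:10]):
                assert getattr(comp, name) == pytest.approx(want, abs=1e-9), name
            assert soil.De == pytest.approx(oracle[10], abs=1e-9)
            de = soil.De

    def test_zero_et0_means_zero_etc(self):
        w = make_weather(Rn=3.0, G=3.0, es=2.0, ea=2.0)
        comp = daily_etc(w, self.make_crop(), SoilEvapState())
        assert comp.ETc == 0.0

    def test_unstressed_dense_canopy_limit(self):
        w = make_weather()
        comp = daily_etc(w, self.make_crop(CWSI=0.0, LAI=12.0), SoilEvapState())
        # Ks = 1 and Kcb_a ~ Kcb_adjust; Ke bounded by its cap
        assert comp.Ks == 1.0
        assert comp.Kcb_a == pytest.approx(comp.Kcb_adjust, abs=1e-3)
        assert comp.Ke <= comp.few * comp.Kc_max + 1e-12

    def test_etc_non_increasing_in_stress(self):
        w = make_weather()
        etcs = []
        for cwsi in np.linspace(0, 1, 11):
            comp = daily_etc(w, self.make_crop(CWSI=float(cwsi)), SoilEvapState())
            etcs.append(comp.ETc)
        assert all(b <= a + 1e-12 for a, b in zip(etcs, etcs[1:]))

    def test_ke_non_increasing_in_depletion(self):
        w = make_weather()
        kes = []
        for de in np.linspace(0, 22, 12):
            soil = SoilEvapState(De=float(de))
            kes.append(daily_etc(w, self.make_crop(), soil).Ke)
        assert all(b <= a + 1e-12 for a, b in zip(kes, kes[1:]))

    def test_total_kc_bounded_by_kc_max(self):
        w = make_weather()
        for cwsi in (0.0, 0.3, 0.9):
            comp = daily_etc(w, self.make_crop(CWSI=cwsi), SoilEvapState())
            assert comp.Ks * comp.Kcb_a + comp.Ke <= comp.Kc_max + 1e-9

    def test_cumulate(self):
        w = make_weather()
        comps = [daily_etc(w, self.make_crop(), SoilEvapState()) for _ in range(10)]
        assert cumulate_et(comps) == pytest.approx(10 * comps[0].ETc)
        assert cumulate_et(comps[:1]) == comps[0].ETc
        with pytest.raises(ValueError):
            cumulate_et([])

    def test_fixture_season_daily_etc_in_reported_stage_ranges(self, full_experiment):
        """Stage-mean daily ETc on the synthetic campaign falls inside the
        range winter-wheat field studies report for that stage."""
        _, truth, _ = full_experiment
        from cropwater.io import read_weather_table  # noqa: F401 (documented path)

        reported = {
            "jointing": (0.401, 3.851),
            "heading": (1.792, 4.444),
            "grain_filling": (2.683, 4.162),
        }
        records = [
            make_weather(date=r.date, T=r.t_mean_c, u2=r.u2_ms, RH_min=r.rh_min_pct,
                         Rn=r.rn_mj, G=r.g_mj, es=r.es_kpa, ea=r.ea_kpa,
                         Delta=float("nan"), gamma=float("nan"))
            for r in truth.weather.itertuples(index=False)
        ]
        for stage, (lo_mm, hi_mm) in reported.items():
            lo, hi = truth.stage_windows[stage]
            vals = []
            for r in truth.stage_table(stage).itertuples(index=False):
                crop = CropState(stage=stage, Kcb_tab=1.15, h=r.height_m,
                                 h_max=r.height_m, LAI=r.lai, CWSI=r.cwsi)
                comps = run_season(records[lo:hi], crop, SoilEvapState())
                vals.extend(c.ETc for c in comps)
            assert lo_mm <= float(np.mean(vals)) <= hi_mm, stage
            assert min(vals) >= 0.0

    def test_run_season_cumulative_non_decreasing_and_wetting_reset(self):
        days = [make_weather(date=f"d{i}") for i in range(12)]
        comps = run_season(days, self.make_crop(), SoilEvapState(), wetting_dates={"d6"})
        cums = [c.ETc_cum for c in comps]
        assert all(b >= a for a, b in zip(cums, cums[1:]))
        # Kr recovers to 1 on the wetting day after prior depletion
        assert comps[6].Kr == 1.0
        assert comps[5].Kr <= comps[0].Kr
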