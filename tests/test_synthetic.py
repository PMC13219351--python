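import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from cropwater import synthetic
from cropwater.et import penman_monteith_et0
from cropwater.io import zonal_band_means, zonal_pixels
from cropwater.structure import aih_height, fit_ground_plane, normalize_cloud
from cropwater.synthetic import (
    STAGE_ENVELOPES,
    STAGES,
    TREATMENT_DEPTHS_MM,
    generate_field_layout,
    generate_truth,
    generate_weather_series,
    render_scene,
)


class TestLayout:
    def test_full_design_counts(self):
        layout = generate_field_layout(30, (1.4, 4.0), seed=1)
        assert len(layout.plots) == 180
        assert layout.plots["treatment"].value_counts().eq(30).all()

    def test_minimal_design(self):
        layout = generate_field_layout(1, (1.4, 4.0), seed=1)
        assert len(layout.plots) == 6
        assert set(layout.plots["treatment"]) == set(TREATMENT_DEPTHS_MM)

    def test_plots_disjoint(self):
        layout = generate_field_layout(4, seed=2)
        polys = list(layout.polygons().values())
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                assert not polys[i].intersects(polys[j])

    def test_determinism(self):
        a = generate_field_layout(5, seed=9).plots
        b = generate_field_layout(5, seed=9).plots
        pd.testing.assert_frame_equal(a, b)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            generate_field_layout(0)
        with pytest.raises(ValueError):
            generate_field_layout(2, (0.0, 4.0))


class TestWeather:
    def test_field_ranges(self):
        w = generate_weather_series(90, seed=7)
        assert len(w) == 90
        assert w["t_mean_c"].between(0, 35).all()
        assert w["u2_ms"].between(0.3, 6).all()
        assert w["rh_min_pct"].between(20, 90).all()
        assert (w["rn_mj"] >= w["g_mj"]).all()
        assert (w["es_kpa"] >= w["ea_kpa"]).all()
        assert (w["ea_kpa"] > 0).all()

    def test_determinism(self):
        pd.testing.assert_frame_equal(
            generate_weather_series(1, seed=0), generate_weather_series(1, seed=0)
        )

    def test_reference_et_downstream_positive(self):
        from cropwater.io import read_weather_table

        w = generate_weather_series(30, seed=3)
        records = [
            r for r in _records(w)
        ]
        et0 = [penman_monteith_et0(r) for r in records]
        assert np.mean(et0) > 0
        assert np.isfinite(et0).all()


def _records(w):
    from cropwater.et import WeatherRecord

    return [
        WeatherRecord(date=r.date, T=r.t_mean_c, u2=r.u2_ms, RH_min=r.rh_min_pct,
                      Rn=r.rn_mj, G=r.g_mj, es=r.es_kpa, ea=r.ea_kpa)
        for r in w.itertuples(index=False)
    ]


class TestTruth:
    def test_noiseless_pmc_ordering(self):
        layout = generate_field_layout(2, seed=4)
        truth = generate_truth(layout, noise=0.0, seed=4)
        t = truth.table
        for stage in STAGES:
            sub = t[t["stage"] == stage].groupby("treatment")["pmc"].mean()
            assert sub["W1"] > sub["W2"] > sub["W3"] > sub["W4"] > sub["W5"] > sub["W6"]

    def test_pmc_declines_across_stages(self):
        layout = generate_field_layout(2, seed=4)
        truth = generate_truth(layout, noise=0.0, seed=4)
        by = truth.table.pivot_table(index="plot_id", columns="stage", values="pmc")
        assert (by["jointing"] > by["heading"]).all()
        assert (by["heading"] > by["grain_filling"]).all()

    def test_wue_identity_exact(self):
        layout = generate_field_layout(2, seed=4)
        truth = generate_truth(layout, wue_true=2.0, noise=0.0, seed=4)
        recovered = (truth.table["biomass"] / truth.table["cum_transpiration"]).to_numpy()
        assert recovered == pytest.approx(np.full(len(recovered), 2.0), rel=1e-14)

    def test_rank_correlation_depth_vs_pmc(self):
        layout = generate_field_layout(30, seed=6)
        truth = generate_truth(layout, seed=6)
        t = truth.table[truth.table["stage"] == "heading"]
        means = t.groupby("treatment")["pmc"].mean()
        depths = pd.Series(TREATMENT_DEPTHS_MM)
        rho = spearmanr(depths[means.index], means).statistic
        assert rho >= 0.9

    def test_envelopes_respected(self):
        layout = generate_field_layout(10, seed=5)
        truth = generate_truth(layout, seed=5)
        for stage in STAGES:
            sub = truth.table[truth.table["stage"] == stage]
            lo, hi, _ = STAGE_ENVELOPES[stage]["lai"]
            assert sub["lai"].between(lo, hi).all()
            h_lo, h_hi, _ = STAGE_ENVELOPES[stage]["height"]
            assert sub["height_m"].between(h_lo, h_hi).all()

    def test_unknown_stage_rejected(self):
        layout = generate_field_layout(1, seed=0)
        with pytest.raises(ValueError, match="tillering"):
            generate_truth(layout, stages=("tillering",))

    def test_determinism(self):
        layout = generate_field_layout(3, seed=8)
        a = generate_truth(layout, seed=8).table
        b = generate_truth(layout, seed=8).table
        pd.testing.assert_frame_equal(a, b)


class TestScene:
    def test_degenerate_noise_thermal_pixels_equal_truth(self, small_layout, small_truth):
        scene = render_scene(
            small_truth, small_layout, "heading",
            ground_sigma=0.0, thermal_sigma=0.0, seed=1,
        )
        pixels = zonal_pixels(scene.thermal, scene.transform, small_layout.polygons())
        expected = small_truth.stage_table("heading").set_index("plot_id")["canopy_temp_mean"]
        for plot_id, vals in pixels.items():
            assert vals == pytest.approx(np.full(len(vals), expected.loc[plot_id]))

    def test_thermal_within_air_band(self, small_layout, small_truth):
        scene = render_scene(small_truth, small_layout, "jointing", seed=1)
        assert np.abs(scene.thermal - scene.air_temp).max() < 15.0

    def test_reflectance_valid_and_ndvi_tracks_lai(self, full_experiment):
        layout, truth, scenes = full_experiment
        scene = scenes["jointing"]
        assert scene.reflectance.min() >= 0.0 and scene.reflectance.max() <= 1.0
        means = zonal_band_means(scene.reflectance, scene.transform, layout.polygons())
        ndvi = (means["NIR"] - means["R"]) / (means["NIR"] + means["R"])
        lai = truth.stage_table("jointing").set_index("plot_id")["lai"]
        r = np.corrcoef(ndvi[lai.index], lai)[0, 1]
        assert r >= 0.8

    def test_aih_height_recovery_rmse(self, full_experiment):
        """95th-percentile heights of the rendered cloud track true height."""
        layout, truth, scenes = full_experiment
        scene = scenes["heading"]
        plane = fit_ground_plane(scene.ground_points)
        cloud = scene.point_cloud
        true_h = truth.stage_table("heading").set_index("plot_id")["height_m"]
        errors = []
        for rec in layout.plots.head(50).itertuples(index=False):
            sel = (
                (cloud[:, 0] >= rec.x0) & (cloud[:, 0] <= rec.x1)
                & (cloud[:, 1] >= rec.y0) & (cloud[:, 1] <= rec.y1)
            )
            est = aih_height(normalize_cloud(cloud[sel], plane), 95)
            errors.append(est - true_h.loc[rec.plot_id])
        rmse_cm = 100.0 * float(np.sqrt(np.mean(np.square(errors))))
        assert rmse_cm <= 3.25

    def test_missing_stage_rejected(self, small_layout, small_truth):
        truth = generate_truth(small_layout, stages=("heading",), seed=5)
        with pytest.raises(ValueError, match="jointing"):
            render_scene(truth, small_layout, "jointing", seed=0)

    def test_scene_determinism(self, small_layout, small_truth):
        a = render_scene(small_truth, small_layout, "heading", seed=2)
        b = render_scene(small_truth, small_layout, "heading", seed=2)
        assert np.array_equal(a.reflectance, b.reflectance)
        assert np.array_equal(a.thermal, b.thermal)
        assert np.array_equal(a.point_cloud, b.point_cloud)
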