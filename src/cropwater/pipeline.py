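"""End-to-end orchestration: simulate -> indices -> ... -> prescription.

``run_pipeline`` executes the eight stages on a synthetic experiment (or a
user-supplied scene set), writing one CSV per stage plus a machine-readable
manifest (seed, config hash, stage outputs) into the run directory:

1. simulate  — field layout, weather, ground truth, per-stage scenes
2. thermal   — per-plot canopy-temperature stats, delta_T and CWSI
3. indices   — per-plot band means and the 18 vegetation indices
4. height    — ground-plane fit and AIH-percentile crop height
5. lai       — six-VI random-forest LAI inversion
6. et        — daily dual-Kc ET per plot, cumulative to each flight date
7. pmc       — multimodal PMC regression accuracy matrix
8. wue       — WUE-PMC quadratic fits, stage thresholds, prescriptions

Ground-truth "field measurements" (LAI, PMC, biomass) carry seeded
multiplicative measurement noise on top of the generator truth, emulating
destructive sampling; the truth table itself keeps the exact construction
identities.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cwio
from . import synthetic
from .et import STATIC_KCB, CropState, SoilEvapState, run_season
from .indices import BandReflectance, compute_all
from .regression import run_matrix
from .structure import aih_height, fit_ground_plane, fit_lai_model, normalize_cloud, predict_lai
from .thermal import thermal_record
from .wue import fit_wue_pmc, optimal_pmc_threshold, prescribe, wue_from_biomass

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "assemble_observations"]

STAGE_NAMES = ("simulate", "thermal", "indices", "height", "lai", "et", "pmc", "wue")


@dataclass
class PipelineConfig:
    """Declarative settings for one end-to-end run."""

    seed: int = 0
    n_plots_per_treatment: int = 5
    stages: tuple[str, ...] = synthetic.STAGES
    n_days: int = 90
    wue_true: float | dict = 2.0
    noise: float = 0.03
    measurement_noise: float = 0.03   # relative sd of simulated field sampling
    aih_percentile: float = 95.0
    # ET constants
    kcb_tab: float = 1.15
    k_attenuation: float = 0.7
    kc_min: float = 0.15
    rew_mm: float = 8.0
    tew_mm: float = 22.0
    fw: float = 1.0
    static_kcb: bool = False
    wetting_interval_days: int = 10   # irrigation/rain events resetting De
    # ML settings
    algorithms: tuple[str, ...] = ("RFR",)
    combos: tuple[str, ...] = ("VIs", "ET", "VIs+ET", "VIs+TIs", "VIs+TIs+ET")
    n_folds: int = 5
    search_budget: int = 0
    write_rasters: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("stages", "algorithms", "combos"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def assemble_observations(layout, truth, scenes) -> pd.DataFrame:
    """Per-plot observation table straight from rendered scenes (no files).

    One row per plot x stage with the 18 vegetation indices, delta_T and
    CWSI from the thermal raster, stage-cumulative dual-Kc ETc, the
    generator's true PMC/LAI/height, and the treatment label. This is the
    in-memory equivalent of the thermal -> indices -> et -> join stages.
    """
    from .et import WeatherRecord

    polys = layout.polygons()
    records = [
        WeatherRecord(date=r.date, T=r.t_mean_c, u2=r.u2_ms, RH_min=r.rh_min_pct,
                      Rn=r.rn_mj, G=r.g_mj, es=r.es_kpa, ea=r.ea_kpa)
        for r in truth.weather.itertuples(index=False)
    ]
    rows = []
    for stage, scene in scenes.items():
        means = cwio.zonal_band_means(scene.reflectance, scene.transform, polys)
        tpix = cwio.zonal_pixels(scene.thermal, scene.transform, polys)
        stage_truth = truth.stage_table(stage).set_index("plot_id")
        _, hi = truth.stage_windows[stage]
        for plot_id, r in means.iterrows():
            bands = BandReflectance(G=r["G"], R=r["R"], RE=r["RE"], NIR=r["NIR"])
            trec = thermal_record(plot_id, tpix[plot_id], scene.air_temp)
            vis = compute_all(bands, ts=trec.t_canopy_mean)
            st = stage_truth.loc[plot_id]
            crop = CropState(
                stage=stage, Kcb_tab=1.15, h=float(st.height_m),
                h_max=float(st.height_m), LAI=float(st.lai), CWSI=trec.cwsi,
            )
            comps = run_season(records[:hi], crop, SoilEvapState())
            rows.append(
                {
                    "plot_id": plot_id, "stage": stage, "treatment": st.treatment,
                    **vis, "delta_t": trec.delta_t, "cwsi": trec.cwsi,
                    "etc_cum": comps[-1].ETc_cum, "pmc": float(st.pmc),
                    "lai_true": float(st.lai), "height_true": float(st.height_m),
                }
            )
    return pd.DataFrame(rows)


def _simulate(cfg: PipelineConfig, out: Path):
    layout = synthetic.generate_field_layout(cfg.n_plots_per_treatment, seed=cfg.seed)
    truth = synthetic.generate_truth(
        layout, cfg.stages, wue_true=cfg.wue_true, seed=cfg.seed,
        noise=cfg.noise, n_days=cfg.n_days,
    )
    scenes = {
        s: synthetic.render_scene(truth, layout, s, seed=cfg.seed) for s in cfg.stages
    }
    cwio.write_plots_geojson(
        out / "plots.geojson", layout.polygons(),
        {r.plot_id: {"treatment": r.treatment} for r in layout.plots.itertuples(index=False)},
    )
    cwio.write_weather_table(out / "weather.csv", truth.weather)
    truth.table.to_csv(out / "truth.csv", index=False)
    if cfg.write_rasters:
        for s, sc in scenes.items():
            cwio.write_raster(out / f"reflectance_{s}.tif", sc.reflectance, sc.transform)
            cwio.write_raster(out / f"thermal_{s}.tif", sc.thermal, sc.transform)
            cwio.write_point_cloud(out / f"cloud_{s}.csv", sc.point_cloud)
    return layout, truth, scenes, out / "truth.csv"


def _thermal_stage(cfg, layout, truth, scenes, out: Path) -> pd.DataFrame:
    polys = layout.polygons()
    rows = []
    for stage, scene in scenes.items():
        pixels = cwio.zonal_pixels(scene.thermal, scene.transform, polys)
        for plot_id, vals in pixels.items():
            rec = thermal_record(plot_id, vals, scene.air_temp)
            rows.append(
                {
                    "plot_id": plot_id, "stage": stage,
                    "t_canopy_mean": rec.t_canopy_mean, "t_wet": rec.t_wet,
                    "t_dry": rec.t_dry, "delta_t": rec.delta_t, "cwsi": rec.cwsi,
                    "degenerate": rec.degenerate,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(out / "thermal.csv", index=False)
    return df


def _indices_stage(cfg, layout, scenes, thermal_df, out: Path) -> pd.DataFrame:
    polys = layout.polygons()
    tmean = thermal_df.set_index(["stage", "plot_id"])["t_canopy_mean"]
    rows = []
    for stage, scene in scenes.items():
        means = cwio.zonal_band_means(scene.reflectance, scene.transform, polys)
        for plot_id, r in means.iterrows():
            bands = BandReflectance(G=r["G"], R=r["R"], RE=r["RE"], NIR=r["NIR"])
            vis = compute_all(bands, ts=float(tmean.loc[(stage, plot_id)]))
            rows.append({"plot_id": plot_id, "stage": stage, **r.to_dict(), **vis})
    df = pd.DataFrame(rows)
    df.to_csv(out / "indices.csv", index=False)
    return df


def _height_stage(cfg, layout, scenes, out: Path) -> pd.DataFrame:
    rows = []
    for stage, scene in scenes.items():
        plane = fit_ground_plane(scene.ground_points)
        cloud = scene.point_cloud
        for rec in layout.plots.itertuples(index=False):
            sel = (
                (cloud[:, 0] >= rec.x0) & (cloud[:, 0] <= rec.x1)
                & (cloud[:, 1] >= rec.y0) & (cloud[:, 1] <= rec.y1)
            )
            z_prime = normalize_cloud(cloud[sel], plane)
            rows.append(
                {
                    "plot_id": rec.plot_id, "stage": stage,
                    "height_m": aih_height(z_prime, cfg.aih_percentile),
                    "n_points": int(sel.sum()),
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(out / "heights.csv", index=False)
    return df


def _lai_stage(cfg, truth, vi_df, out: Path) -> pd.DataFrame:
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(101,))
    )
    merged = vi_df.merge(
        truth.table[["plot_id", "stage", "lai"]], on=["plot_id", "stage"]
    )
    lai_obs = merged["lai"].to_numpy() * (
        1.0 + cfg.measurement_noise * rng.standard_normal(len(merged))
    )
    model = fit_lai_model(merged, lai_obs, seed=cfg.seed)
    merged["lai_pred"] = predict_lai(model, merged)
    result = merged[["plot_id", "stage", "lai_pred"]].copy()
    result["model_r2"] = model.r2
    result["model_rmse"] = model.rmse
    result.to_csv(out / "lai.csv", index=False)
    return result


def _et_stage(cfg, truth, thermal_df, height_df, lai_df, out: Path) -> pd.DataFrame:
    weather = cwio.read_weather_table(out / "weather.csv")
    cwsi = thermal_df.set_index(["stage", "plot_id"])["cwsi"]
    height = height_df.set_index(["stage", "plot_id"])["height_m"]
    lai = lai_df.set_index(["stage", "plot_id"])["lai_pred"]
    wetting = {
        weather[i].date for i in range(0, len(weather), max(cfg.wetting_interval_days, 1))
    }
    daily_rows, cum_rows = [], []
    plot_ids = sorted(set(thermal_df["plot_id"]))
    for plot_id in plot_ids:
        soil = SoilEvapState(REW=cfg.rew_mm, TEW=cfg.tew_mm, fw=cfg.fw)
        cum = 0.0
        for stage in cfg.stages:
            lo, hi = truth.stage_windows[stage]
            h = float(height.loc[(stage, plot_id)])
            crop = CropState(
                stage=stage,
                Kcb_tab=cfg.kcb_tab if not cfg.static_kcb else STATIC_KCB.get(stage, cfg.kcb_tab),
                h=h,
                h_max=max(
                    float(height.loc[(s, plot_id)]) for s in cfg.stages
                ),
                LAI=float(lai.loc[(stage, plot_id)]),
                CWSI=float(cwsi.loc[(stage, plot_id)]),
                k=cfg.k_attenuation,
                Kc_min=cfg.kc_min,
            )
            comps = run_season(
                weather[lo:hi], crop, soil,
                wetting_dates=wetting, static_kcb=cfg.static_kcb,
            )
            for w, c in zip(weather[lo:hi], comps):
                daily_rows.append(
                    {
                        "plot_id": plot_id, "stage": stage, "date": w.date,
                        "ET0": c.ET0, "Kcb_adjust": c.Kcb_adjust, "Kcb_a": c.Kcb_a,
                        "Ks": c.Ks, "Kc_max": c.Kc_max, "fc": c.fc, "few": c.few,
                        "Kr": c.Kr, "Ke": c.Ke, "ETc": c.ETc,
                    }
                )
            cum += comps[-1].ETc_cum
            cum_rows.append({"plot_id": plot_id, "stage": stage, "etc_cum": cum})
    daily = pd.DataFrame(daily_rows)
    daily.to_csv(out / "et_daily.csv", index=False)
    cum_df = pd.DataFrame(cum_rows)
    cum_df.to_csv(out / "et.csv", index=False)
    return cum_df


def _pmc_stage(cfg, truth, vi_df, thermal_df, et_df, out: Path) -> pd.DataFrame:
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(102,))
    )
    obs = (
        vi_df.merge(thermal_df[["plot_id", "stage", "delta_t", "cwsi"]], on=["plot_id", "stage"])
        .merge(et_df, on=["plot_id", "stage"])
        .merge(truth.table[["plot_id", "stage", "pmc"]], on=["plot_id", "stage"])
    )
    obs["pmc"] = np.clip(
        obs["pmc"] * (1.0 + cfg.measurement_noise * rng.standard_normal(len(obs))),
        0.001, 0.999,
    )
    obs.to_csv(out / "observations.csv", index=False)
    table = run_matrix(
        obs, cfg.stages, algorithms=cfg.algorithms, combos=cfg.combos,
        seed=cfg.seed, n_folds=cfg.n_folds, search_budget=cfg.search_budget,
    )
    table.to_csv(out / "pmc_matrix.csv", index=False)
    return obs


def _wue_stage(cfg, truth, obs, out: Path) -> pd.DataFrame:
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(103,))
    )
    t = truth.table.copy()
    biomass_obs = t["biomass"].to_numpy() * (
        1.0 + cfg.measurement_noise * rng.standard_normal(len(t))
    )
    t["wue_obs"] = [
        wue_from_biomass(b, ct) for b, ct in zip(biomass_obs, t["cum_transpiration"])
    ]
    pmc_obs = obs.set_index(["stage", "plot_id"])["pmc"]
    t["pmc_pct"] = [
        100.0 * float(pmc_obs.loc[(s, p)]) for s, p in zip(t["stage"], t["plot_id"])
    ]
    fit_rows, thresholds = [], {}
    for stage in cfg.stages:
        best_opt, best_thr = -np.inf, None
        for treatment in sorted(set(t["treatment"])):
            sub = t[(t["stage"] == stage) & (t["treatment"] == treatment)]
            if len(sub) < 4:
                continue
            fit = fit_wue_pmc(
                zip(sub["pmc_pct"], sub["wue_obs"]), "quadratic", treatment, stage
            )
            domain = (float(sub["pmc_pct"].min()), float(sub["pmc_pct"].max()))
            if domain[0] >= domain[1]:
                continue
            thr = optimal_pmc_threshold(fit, domain)
            opt_wue = float(fit.predict(thr))
            a = fit.coefficients[0]
            fit_rows.append(
                {
                    "stage": stage, "treatment": treatment, "form": "quadratic",
                    "a": a, "b": fit.coefficients[1], "c": fit.coefficients[2],
                    "r2": fit.r2, "pmc_threshold": thr, "wue_at_threshold": opt_wue,
                    "interior_optimum": bool(a < 0 and domain[0] <= -fit.coefficients[1] / (2 * a) <= domain[1]),
                }
            )
            if opt_wue > best_opt:
                best_opt, best_thr = opt_wue, thr
        if best_thr is not None:
            thresholds[stage] = best_thr
        else:
            # too few plots per treatment for a quadratic: fall back to the
            # observed PMC at the highest observed WUE
            sub = t[t["stage"] == stage]
            thresholds[stage] = round(
                float(sub.loc[sub["wue_obs"].idxmax(), "pmc_pct"]), 1
            )
            logger.warning("stage %s: no quadratic fit possible, empirical threshold used", stage)
    fits = pd.DataFrame(fit_rows)
    fits.to_csv(out / "wue_fits.csv", index=False)
    pd.DataFrame(
        [{"stage": s, "pmc_threshold_pct": v} for s, v in thresholds.items()]
    ).to_csv(out / "thresholds.csv", index=False)
    pred = obs[["plot_id", "stage", "pmc"]].copy()
    pred["pmc_pct"] = 100.0 * pred.pop("pmc")
    prescription = prescribe(thresholds, pred)
    prescription.to_csv(out / "prescription.csv", index=False)
    return fits


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run all eight stages; returns the run directory containing a manifest.

    Identical config + seed give identical outputs. Any stage failure
    aborts with the stage name in the raised error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, list[str]] = {}
    stage = "simulate"
    try:
        layout, truth, scenes, _ = _simulate(config, out)
        outputs["simulate"] = ["plots.geojson", "weather.csv", "truth.csv"]
        stage = "thermal"
        thermal_df = _thermal_stage(config, layout, truth, scenes, out)
        outputs["thermal"] = ["thermal.csv"]
        stage = "indices"
        vi_df = _indices_stage(config, layout, scenes, thermal_df, out)
        outputs["indices"] = ["indices.csv"]
        stage = "height"
        height_df = _height_stage(config, layout, scenes, out)
        outputs["height"] = ["heights.csv"]
        stage = "lai"
        lai_df = _lai_stage(config, truth, vi_df, out)
        outputs["lai"] = ["lai.csv"]
        stage = "et"
        et_df = _et_stage(config, truth, thermal_df, height_df, lai_df, out)
        outputs["et"] = ["et.csv", "et_daily.csv"]
        stage = "pmc"
        obs = _pmc_stage(config, truth, vi_df, thermal_df, et_df, out)
        outputs["pmc"] = ["observations.csv", "pmc_matrix.csv"]
        stage = "wue"
        _wue_stage(config, truth, obs, out)
        outputs["wue"] = ["wue_fits.csv", "thresholds.csv", "prescription.csv"]
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "stages": {name: outputs[name] for name in STAGE_NAMES},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    for files in outputs.values():
        for f in files:
            if not (out / f).exists() or (out / f).stat().st_size == 0:
                raise RuntimeError(f"declared output {f} missing or empty")
    return out
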