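"""In-silico winter-wheat irrigation experiment.

Generates everything the pipeline consumes, with the statistical structure
the analysis assumes: a plot grid under six irrigation treatments (W1-W6,
282 down to 0 mm), a daily weather series, per-plot ground truth driven by
a latent water-status variable in [0, 1], and per-stage scenes (4-band
reflectance raster, thermal raster, 3-D point cloud).

The causal chain mirrors the field experiment: irrigation depth sets latent
water status s; s raises plant moisture content, LAI and height (within
stage envelopes), cools the canopy (T_c = T_a + dT_max (1 - s) + offset),
and lowers the water-stress index. Reflectance mixes a soil and a dense
canopy endmember linearly in LAI so NDVI-family indices track LAI; thermal
pixels inside a plot are Gaussian about the plot canopy temperature; canopy
point heights are drawn so their 95th percentile matches true height.
Biomass is constructed as WUE times cumulative transpiration exactly, so
the WUE inversion recovers the generator's value to machine precision on
noiseless draws.

All randomness flows from one root seed through named substreams, so each
artifact can be regenerated independently and byte-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as _beta_dist
from shapely.geometry import Polygon, box

from .et import (
    WeatherRecord,
    adjust_kcb_climate,
    ks_from_cwsi,
    penman_monteith_et0,
    saturation_vapor_pressure,
    scale_kcb_lai,
)

__all__ = [
    "TREATMENT_DEPTHS_MM",
    "STAGES",
    "STAGE_ENVELOPES",
    "FieldLayout",
    "SyntheticTruth",
    "SceneBundle",
    "generate_field_layout",
    "generate_weather_series",
    "generate_truth",
    "render_scene",
]

TREATMENT_DEPTHS_MM: dict[str, float] = {
    "W1": 282.0, "W2": 254.0, "W3": 198.0, "W4": 141.0, "W5": 85.0, "W6": 0.0,
}

STAGES: tuple[str, ...] = ("jointing", "heading", "grain_filling")

# Per-stage plausibility envelopes (min, max, mean): LAI and height (m),
# from the field statistics the generator is calibrated to.
STAGE_ENVELOPES = {
    "jointing": {"lai": (3.10, 3.59, 3.41), "height": (0.38, 0.61, 0.50)},
    "heading": {"lai": (5.09, 5.34, 5.27), "height": (0.63, 0.91, 0.76)},
    "grain_filling": {"lai": (4.78, 5.15, 4.94), "height": (0.62, 0.96, 0.79)},
}

# PMC (fraction) at latent water status s, per stage: base + span * s.
# Bases decline stage over stage, reproducing the season-long PMC decline.
_PMC_CURVES = {
    "jointing": (0.70, 0.20),
    "heading": (0.62, 0.22),
    "grain_filling": (0.48, 0.24),
}

# canopy warming at full stress (s = 0) relative to air temperature, deg C;
# well-watered canopies sit slightly below air temperature
_DT_MAX = 8.0
_DT_OFFSET = -2.0

# thermal stress index of the truth table: moderate baseline plus stress term
_CWSI_BASE, _CWSI_SPAN = 0.15, 0.55

# basal crop coefficient used for the generator's transpiration bookkeeping
_KCB_TAB_MID = 1.15

# soil / dense-canopy reflectance endmembers in band order (G, R, RE, NIR)
_SOIL_SPECTRUM = np.array([0.12, 0.18, 0.22, 0.25])
_CANOPY_SPECTRUM = np.array([0.08, 0.04, 0.30, 0.50])
_LAI_FULL_COVER = 6.0  # LAI at which the linear soil->canopy mixing saturates

# Beta(6, 2) height-shape divisor: its own 95th percentile, so the rescaled
# draws have a 95th percentile equal to true height by construction
_BETA_A, _BETA_B = 6.0, 2.0
_BETA_Q95 = float(_beta_dist.ppf(0.95, _BETA_A, _BETA_B))

_SUBSTREAMS = {"layout": 1, "weather": 2, "truth": 3, "scene": 4}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_SUBSTREAMS[stream], extra))
    )


@dataclass(frozen=True)
class FieldLayout:
    """Plot polygons with their treatment labels and irrigation depths."""

    plots: pd.DataFrame                 # columns: plot_id, treatment, x0, y0, x1, y1
    treatment_depths: dict[str, float]
    plot_size: tuple[float, float]

    def polygon(self, plot_id: str) -> Polygon:
        r = self.plots.set_index("plot_id").loc[plot_id]
        return box(r.x0, r.y0, r.x1, r.y1)

    def polygons(self) -> dict[str, Polygon]:
        return {
            r.plot_id: box(r.x0, r.y0, r.x1, r.y1)
            for r in self.plots.itertuples(index=False)
        }

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        p = self.plots
        return float(p.x0.min()), float(p.y0.min()), float(p.x1.max()), float(p.y1.max())


@dataclass(frozen=True)
class SyntheticTruth:
    """Per plot x stage ground truth plus the weather that produced it."""

    table: pd.DataFrame       # plot_id, treatment, stage, latent, pmc, lai,
                              # height_m, canopy_temp_mean, cwsi, cum_transpiration,
                              # biomass, wue
    weather: pd.DataFrame     # daily weather in the I/O schema
    stage_windows: dict[str, tuple[int, int]]   # stage -> [start_day, end_day)
    stage_air_temp: dict[str, float]            # flight-date air temperature

    def stage_table(self, stage: str) -> pd.DataFrame:
        if stage not in set(self.table["stage"]):
            raise ValueError(f"stage {stage!r} not in truth")
        return self.table[self.table["stage"] == stage].reset_index(drop=True)


@dataclass(frozen=True)
class SceneBundle:
    """One stage's rendered rasters and point cloud in the field frame."""

    stage: str
    reflectance: np.ndarray       # (H, W, 4) float, bands G, R, RE, NIR in [0, 1]
    thermal: np.ndarray           # (H, W) float, deg C
    transform: tuple[float, float, float]   # (x_left, y_top, resolution_m)
    point_cloud: np.ndarray       # (N, 3) canopy + ground returns
    ground_points: np.ndarray     # (M, 3) bare-ground survey returns
    air_temp: float               # deg C on the flight date


def generate_field_layout(
    n_plots_per_treatment: int,
    plot_size: tuple[float, float] = (1.4, 4.0),
    seed: int = 0,
    alley: float = 0.6,
) -> FieldLayout:
    """Disjoint rectangular plots on a regular grid, treatments shuffled.

    ``6 * n_plots_per_treatment`` plots of ``plot_size`` (width, length in
    m) separated by ``alley`` m, with the six treatment labels assigned by a
    seeded shuffle.
    """
    if n_plots_per_treatment < 1:
        raise ValueError("n_plots_per_treatment must be >= 1")
    w, l = plot_size
    if w <= 0 or l <= 0:
        raise ValueError("plot dimensions must be positive")
    n_total = 6 * n_plots_per_treatment
    labels = np.repeat(list(TREATMENT_DEPTHS_MM), n_plots_per_treatment)
    _rng(seed, "layout").shuffle(labels)
    n_cols = min(n_total, 15)
    rows = []
    for i, treatment in enumerate(labels):
        r, c = divmod(i, n_cols)
        x0 = c * (w + alley)
        y0 = r * (l + alley)
        rows.append(
            {
                "plot_id": f"P{i + 1:03d}",
                "treatment": treatment,
                "x0": x0,
                "y0": y0,
                "x1": x0 + w,
                "y1": y0 + l,
            }
        )
    return FieldLayout(pd.DataFrame(rows), dict(TREATMENT_DEPTHS_MM), plot_size)


def generate_weather_series(
    n_days: int, seed: int = 0, start: str = "2023-03-01"
) -> pd.DataFrame:
    """Daily spring weather with internally consistent vapor pressures.

    Mean temperature ramps from ~9 to ~22 deg C with day-to-day noise;
    saturation vapor pressure is the mean of the svp at the day's implied
    max/min temperatures and actual vapor pressure sits below the svp at
    the minimum, so es >= ea > 0 always holds and the implied minimum
    relative humidity stays in [20, 90] %.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = _rng(seed, "weather")
    day = np.arange(n_days)
    frac = day / max(n_days - 1, 1)
    t_mean = np.clip(9.0 + 13.0 * frac + rng.normal(0, 1.5, n_days), 0.0, 35.0)
    spread = rng.uniform(5.0, 7.0, n_days)           # half daily temperature range
    u2 = np.clip(rng.lognormal(0.5, 0.4, n_days), 0.3, 6.0)
    rn = np.clip(9.0 + 5.0 * frac + rng.normal(0, 1.2, n_days), 4.0, 22.0)
    g = 0.1 * rn
    es = 0.5 * (
        np.vectorize(saturation_vapor_pressure)(t_mean + spread)
        + np.vectorize(saturation_vapor_pressure)(t_mean - spread)
    )
    ea = np.vectorize(saturation_vapor_pressure)(t_mean - spread) * rng.uniform(
        0.75, 0.95, n_days
    )
    rh_min = np.clip(
        100.0 * ea / np.vectorize(saturation_vapor_pressure)(t_mean + spread), 20.0, 90.0
    )
    dates = pd.date_range(start, periods=n_days, freq="D").strftime("%Y-%m-%d")
    return pd.DataFrame(
        {
            "date": dates,
            "t_mean_c": t_mean,
            "rh_min_pct": rh_min,
            "u2_ms": u2,
            "rn_mj": rn,
            "g_mj": g,
            "es_kpa": es,
            "ea_kpa": ea,
        }
    )


def _weather_records(weather: pd.DataFrame) -> list[WeatherRecord]:
    return [
        WeatherRecord(
            date=r.date, T=r.t_mean_c, u2=r.u2_ms, RH_min=r.rh_min_pct,
            Rn=r.rn_mj, G=r.g_mj, es=r.es_kpa, ea=r.ea_kpa,
        )
        for r in weather.itertuples(index=False)
    ]


def _stage_windows(n_days: int, stages: tuple[str, ...]) -> dict[str, tuple[int, int]]:
    per = n_days // len(STAGES)
    all_windows = {
        s: (i * per, (i + 1) * per if i < len(STAGES) - 1 else n_days)
        for i, s in enumerate(STAGES)
    }
    return {s: all_windows[s] for s in stages}


def generate_truth(
    layout: FieldLayout,
    stages=STAGES,
    wue_true: float | dict[str, float] = 2.0,
    seed: int = 0,
    noise: float = 0.03,
    n_days: int = 90,
) -> SyntheticTruth:
    """Per-plot ground truth consistent with the irrigation gradient.

    Latent water status is irrigation depth (normalized to the deepest
    treatment) plus seeded Gaussian noise of scale ``noise``, clipped to
    [0, 1]. PMC, LAI, height and canopy temperature follow s as documented
    in the module docstring; daily transpiration is Ks * Kcb_a * ET0 on the
    generated weather and biomass is exactly ``wue_true`` times cumulative
    transpiration from emergence to the stage's flight date.
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage labels {unknown}; valid: {list(STAGES)}")
    stages = tuple(stages)
    if isinstance(wue_true, (int, float)):
        wue_map = {t: float(wue_true) for t in TREATMENT_DEPTHS_MM}
    else:
        missing = set(TREATMENT_DEPTHS_MM) - set(wue_true)
        if missing:
            raise ValueError(f"wue_true missing treatments {sorted(missing)}")
        wue_map = {t: float(v) for t, v in wue_true.items()}

    rng = _rng(seed, "truth")
    weather = generate_weather_series(n_days, seed)
    records = _weather_records(weather)
    et0 = np.array([penman_monteith_et0(w) for w in records])
    windows = _stage_windows(n_days, stages)
    max_depth = max(layout.treatment_depths.values())

    plots = layout.plots
    n = len(plots)
    depth_frac = plots["treatment"].map(layout.treatment_depths).to_numpy() / max_depth
    latent = np.clip(depth_frac + rng.normal(0, noise, n), 0.0, 1.0)

    # per-day transpiration coefficient shared within a stage, scaled per
    # plot by its stress factor: T_day = Ks * Kcb_a(LAI) * ET0
    rows = []
    for stage in stages:
        lo, hi, mean = STAGE_ENVELOPES[stage]["lai"]
        lai = np.clip(
            mean + (latent - 0.5) * 0.8 * (hi - lo) + rng.normal(0, noise / 2, n), lo, hi
        )
        h_lo, h_hi, h_mean = STAGE_ENVELOPES[stage]["height"]
        height = np.clip(
            h_mean + (latent - 0.5) * 0.8 * (h_hi - h_lo) + rng.normal(0, noise / 3, n),
            h_lo, h_hi,
        )
        base, span = _PMC_CURVES[stage]
        pmc = np.clip(base + span * latent + rng.normal(0, noise / 3, n), 0.01, 0.99)
        cwsi = np.clip(_CWSI_BASE + _CWSI_SPAN * (1.0 - latent), 0.0, 1.0)
        start, end = windows[stage]
        t_air = float(weather["t_mean_c"].iloc[start:end].mean())
        canopy_t = t_air + _DT_MAX * (1.0 - latent) + _DT_OFFSET

        # cumulative transpiration from emergence (day 0) to stage end
        ks = 1.0 - cwsi
        kcb_a = np.array(
            [
                scale_kcb_lai(
                    adjust_kcb_climate(
                        _KCB_TAB_MID, float(h),
                        float(weather["u2_ms"].iloc[start:end].mean()),
                        float(weather["rh_min_pct"].iloc[start:end].mean()),
                    ),
                    float(l_),
                )
                for h, l_ in zip(height, lai)
            ]
        )
        cum_t = ks * kcb_a * float(et0[:end].sum())
        wue = plots["treatment"].map(wue_map).to_numpy(dtype=float)
        biomass = wue * cum_t
        for i in range(n):
            rows.append(
                {
                    "plot_id": plots["plot_id"].iloc[i],
                    "treatment": plots["treatment"].iloc[i],
                    "stage": stage,
                    "latent": latent[i],
                    "pmc": pmc[i],
                    "lai": lai[i],
                    "height_m": height[i],
                    "canopy_temp_mean": canopy_t[i],
                    "cwsi": cwsi[i],
                    "cum_transpiration": cum_t[i],
                    "biomass": biomass[i],
                    "wue": wue[i],
                }
            )
    stage_air = {
        s: float(weather["t_mean_c"].iloc[windows[s][0]:windows[s][1]].mean())
        for s in stages
    }
    return SyntheticTruth(pd.DataFrame(rows), weather, windows, stage_air)


def _ground_elevation(x, y):
    """The generator's gently tilted terrain surface (m above datum)."""
    return 0.005 * np.asarray(x) + 0.002 * np.asarray(y) + 100.0


def render_scene(
    truth: SyntheticTruth,
    layout: FieldLayout,
    stage: str,
    ground_sigma: float = 0.01,
    seed: int = 0,
    resolution: float = 0.10,
    thermal_sigma: float = 0.8,
    reflectance_sigma: float = 0.01,
    canopy_points: int = 500,
    ground_points_per_plot: int = 100,
    soil_temp_offset: float = 6.0,
) -> SceneBundle:
    """Rasters and point cloud for one stage of the generated truth.

    Reflectance mixes soil and canopy endmembers linearly in LAI (fraction
    LAI / 6, clipped to 1) plus Gaussian pixel noise; thermal pixels inside
    a plot are N(plot canopy temperature, ``thermal_sigma``) on a warm soil
    background; canopy point heights are Beta(6, 2) draws rescaled so their
    95th percentile equals true height, on a tilted ground plane sampled
    with ``ground_sigma`` vertical noise.
    """
    stage_truth = truth.stage_table(stage)   # raises if stage absent
    stage_idx = STAGES.index(stage)
    rng = _rng(seed, "scene", stage_idx)
    x_min, y_min, x_max, y_max = layout.bounds
    margin = 1.0
    x_left, y_top = x_min - margin, y_max + margin
    width = int(math.ceil((x_max - x_min + 2 * margin) / resolution))
    height_px = int(math.ceil((y_max - y_min + 2 * margin) / resolution))

    t_air = truth.stage_air_temp[stage]
    reflectance = (
        _SOIL_SPECTRUM[None, None, :]
        + rng.normal(0, reflectance_sigma, (height_px, width, 4))
    )
    thermal = t_air + soil_temp_offset + rng.normal(0, thermal_sigma, (height_px, width))

    xs = x_left + (np.arange(width) + 0.5) * resolution
    ys = y_top - (np.arange(height_px) + 0.5) * resolution

    cloud_parts, ground_parts = [], []
    by_plot = stage_truth.set_index("plot_id")
    for rec in layout.plots.itertuples(index=False):
        row = by_plot.loc[rec.plot_id]
        cols = np.flatnonzero((xs >= rec.x0) & (xs <= rec.x1))
        rws = np.flatnonzero((ys >= rec.y0) & (ys <= rec.y1))
        if len(cols) and len(rws):
            cover = min(row.lai / _LAI_FULL_COVER, 1.0)
            mixed = _SOIL_SPECTRUM + cover * (_CANOPY_SPECTRUM - _SOIL_SPECTRUM)
            block = rng.normal(0, reflectance_sigma, (len(rws), len(cols), 4))
            reflectance[np.ix_(rws, cols)] = mixed[None, None, :] + block
            thermal[np.ix_(rws, cols)] = row.canopy_temp_mean + (
                rng.normal(0, thermal_sigma, (len(rws), len(cols)))
                if thermal_sigma > 0
                else 0.0
            )
        px = rng.uniform(rec.x0, rec.x1, canopy_points)
        py = rng.uniform(rec.y0, rec.y1, canopy_points)
        pz = _ground_elevation(px, py) + row.height_m * (
            rng.beta(_BETA_A, _BETA_B, canopy_points) / _BETA_Q95
        )
        cloud_parts.append(np.column_stack([px, py, pz]))
        gx = rng.uniform(rec.x0 - 0.3, rec.x1 + 0.3, ground_points_per_plot)
        gy = rng.uniform(rec.y0 - 0.3, rec.y1 + 0.3, ground_points_per_plot)
        gz = _ground_elevation(gx, gy) + (
            rng.normal(0, ground_sigma, ground_points_per_plot) if ground_sigma > 0 else 0.0
        )
        ground_parts.append(np.column_stack([gx, gy, gz]))

    reflectance = np.clip(reflectance, 0.0, 1.0)
    ground = np.concatenate(ground_parts)
    cloud = np.concatenate(cloud_parts + [ground])
    return SceneBundle(
        stage=stage,
        reflectance=reflectance,
        thermal=thermal,
        transform=(x_left, y_top, resolution),
        point_cloud=cloud,
        ground_points=ground,
        air_temp=t_air,
    )
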