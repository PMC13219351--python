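"""Reading, writing and per-plot reduction of the pipeline's file formats.

Rasters are plain TIFF (via tifffile) in a local planar frame; the grid
geometry travels as a ``(x_left, y_top, resolution)`` transform stored in
the TIFF description tag. Pixels follow a half-open model with the origin
at the upper-left corner: the center of pixel (row, col) sits at
``x_left + (col + 0.5) res, y_top - (row + 0.5) res``. Plot polygons are
GeoJSON FeatureCollections; point clouds are XYZ CSV; weather and
observations are CSV with documented headers. Temperatures are deg C
throughout.

Zonal reduction assigns a pixel to a plot when its center falls inside the
polygon (center-in-polygon rule).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import mapping, shape

from .et import WeatherRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PlotObservation",
    "zonal_band_means",
    "zonal_pixels",
    "write_raster",
    "read_raster",
    "write_plots_geojson",
    "read_plots_geojson",
    "read_weather_table",
    "write_weather_table",
    "read_point_cloud",
    "write_point_cloud",
]

WEATHER_COLUMNS = (
    "date", "t_mean_c", "rh_min_pct", "u2_ms", "rn_mj", "g_mj", "es_kpa", "ea_kpa",
)


@dataclass
class PlotObservation:
    """The per-plot join of every upstream product for one growth stage."""

    plot_id: str
    stage: str
    band_means: dict[str, float] | None = None      # G, R, RE, NIR in [0, 1]
    canopy_temp_pixels: np.ndarray | None = None
    height_m: float | None = None
    vi_values: dict[str, float] | None = None
    delta_t: float | None = None
    cwsi: float | None = None
    lai: float | None = None
    etc_cum: float | None = None
    pmc: float | None = None

    def __post_init__(self) -> None:
        if self.band_means is not None:
            for b, v in self.band_means.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"band mean {b}={v} outside [0, 1]")
        if self.pmc is not None and not 0.0 <= self.pmc <= 1.0:
            raise ValueError(f"pmc={self.pmc} outside [0, 1]")


def _pixel_centers(transform: tuple[float, float, float], shape_hw: tuple[int, int]):
    x_left, y_top, res = transform
    xs = x_left + (np.arange(shape_hw[1]) + 0.5) * res
    ys = y_top - (np.arange(shape_hw[0]) + 0.5) * res
    return xs, ys


def zonal_pixels(
    raster: np.ndarray,
    transform: tuple[float, float, float],
    polygons: dict[str, shapely.Geometry],
) -> dict[str, np.ndarray]:
    """In-polygon pixel values per plot (center-in-polygon rule).

    ``raster`` is (H, W) or (H, W, B); the returned arrays are (n,) or
    (n, B). Plots covering no pixel centers map to an empty array with a
    warning.
    """
    arr = np.asarray(raster)
    if arr.ndim not in (2, 3):
        raise ValueError("raster must be (H, W) or (H, W, B)")
    xs, ys = _pixel_centers(transform, arr.shape[:2])
    out: dict[str, np.ndarray] = {}
    for plot_id, poly in polygons.items():
        minx, miny, maxx, maxy = poly.bounds
        cols = np.flatnonzero((xs >= minx) & (xs <= maxx))
        rows = np.flatnonzero((ys >= miny) & (ys <= maxy))
        if len(cols) == 0 or len(rows) == 0:
            logger.warning("plot %s covers no pixel centers", plot_id)
            out[plot_id] = arr[0:0, 0]
            continue
        cc, rr = np.meshgrid(cols, rows)
        inside = shapely.contains_xy(poly, xs[cc.ravel()], ys[rr.ravel()])
        if not inside.any():
            logger.warning("plot %s covers no pixel centers", plot_id)
            out[plot_id] = arr[0:0, 0]
            continue
        out[plot_id] = arr[rr.ravel()[inside], cc.ravel()[inside]]
    return out


def zonal_band_means(
    raster: np.ndarray,
    transform: tuple[float, float, float],
    polygons: dict[str, shapely.Geometry],
    band_names: tuple[str, ...] = ("G", "R", "RE", "NIR"),
) -> pd.DataFrame:
    """Mean in-polygon value per band per plot; NaN for empty plots."""
    arr = np.asarray(raster, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
        band_names = band_names[:1]
    if arr.shape[2] != len(band_names):
        raise ValueError(f"raster has {arr.shape[2]} bands but {len(band_names)} names given")
    pixels = zonal_pixels(arr, transform, polygons)
    rows = []
    for plot_id, vals in pixels.items():
        if vals.size == 0:
            rows.append({"plot_id": plot_id, **{b: np.nan for b in band_names}})
        else:
            means = vals.reshape(-1, arr.shape[2]).mean(axis=0)
            rows.append({"plot_id": plot_id, **dict(zip(band_names, means))})
    return pd.DataFrame(rows).set_index("plot_id")


def write_raster(path, raster: np.ndarray, transform: tuple[float, float, float]) -> None:
    """Write a (H, W[, B]) array as TIFF with the transform in the description."""
    meta = json.dumps({"transform": list(transform)})
    tifffile.imwrite(
        str(path), np.asarray(raster, dtype=np.float32),
        photometric="minisblack", description=meta,
    )


def read_raster(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a TIFF written by :func:`write_raster`; returns (array, transform)."""
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].tags.get("ImageDescription")
        if desc is None:
            raise ValueError(f"{path}: no transform metadata in TIFF description")
        transform = tuple(json.loads(desc.value)["transform"])
    return arr, transform


def write_plots_geojson(path, polygons: dict[str, shapely.Geometry], properties=None) -> None:
    """Plot polygons as a GeoJSON FeatureCollection keyed by plot_id."""
    feats = []
    for plot_id, poly in polygons.items():
        props = {"plot_id": plot_id}
        if properties and plot_id in properties:
            props.update(properties[plot_id])
        feats.append({"type": "Feature", "geometry": mapping(poly), "properties": props})
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_plots_geojson(path) -> tuple[dict[str, shapely.Geometry], dict[str, dict]]:
    """Returns (plot_id -> polygon, plot_id -> extra properties)."""
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    polys, props = {}, {}
    for feat in data["features"]:
        pid = feat["properties"]["plot_id"]
        polys[pid] = shape(feat["geometry"])
        props[pid] = {k: v for k, v in feat["properties"].items() if k != "plot_id"}
    return polys, props


def read_weather_table(path) -> list[WeatherRecord]:
    """Validated daily weather records from CSV.

    Requires the columns ``date, t_mean_c, rh_min_pct, u2_ms, rn_mj, g_mj,
    es_kpa, ea_kpa``; a missing column raises a schema error naming it, and
    a row with ea > es raises a validation error with its index.
    """
    df = pd.read_csv(path)
    for col in WEATHER_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"weather table missing required column '{col}'")
    records = []
    for i, r in enumerate(df.itertuples(index=False)):
        if r.ea_kpa > r.es_kpa:
            raise ValueError(
                f"row {i}: actual vapor pressure ea={r.ea_kpa} exceeds saturation es={r.es_kpa}"
            )
        records.append(
            WeatherRecord(
                date=str(r.date), T=r.t_mean_c, u2=r.u2_ms, RH_min=r.rh_min_pct,
                Rn=r.rn_mj, G=r.g_mj, es=r.es_kpa, ea=r.ea_kpa,
            )
        )
    return records


def write_weather_table(path, weather: pd.DataFrame) -> None:
    missing = [c for c in WEATHER_COLUMNS if c not in weather.columns]
    if missing:
        raise ValueError(f"weather frame missing columns {missing}")
    weather.loc[:, list(WEATHER_COLUMNS)].to_csv(path, index=False)


def read_point_cloud(path) -> np.ndarray:
    """(N, 3) point cloud from an XYZ CSV with columns x, y, z.

    Rows with non-finite coordinates are dropped with a warning; an empty
    file yields an empty (0, 3) array. LAS input is not supported — convert
    to XYZ CSV first.
    """
    path = Path(path)
    if path.suffix.lower() in (".las", ".laz"):
        raise ValueError(f"{path}: LAS/LAZ not supported; provide an XYZ CSV (columns x,y,z)")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty point-cloud file", path)
        return np.empty((0, 3))
    for col in ("x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"point cloud missing required column '{col}'")
    pts = df.loc[:, ["x", "y", "z"]].to_numpy(dtype=float)
    finite = np.isfinite(pts).all(axis=1)
    if not finite.all():
        logger.warning("dropped %d non-finite points", int((~finite).sum()))
    pts = pts[finite]
    logger.info("read %d points from %s", len(pts), path)
    return pts


def write_point_cloud(path, points: np.ndarray) -> None:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    pd.DataFrame(pts, columns=["x", "y", "z"]).to_csv(path, index=False)
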