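"""Canopy structure: point-cloud crop height and random-forest LAI inversion.

Crop height comes from the accumulated-height-histogram (AIH) approach:
ground-normalized point heights are ranked and a high percentile (90/95/99)
of the cumulative distribution is read off as the canopy top; with heights
normalized to ground = 0 the lower boundary defaults to the 0th percentile,
so the percentile difference is the stand height. The 95th percentile is
the default upper bound.

LAI is inverted from six broadly used vegetation indices (RDVI, OSAVI,
VIopt, MNLI, SAVI, NDVI) with a seeded random-forest regressor; accuracy is
reported on a held-out fraction with R^2 / RMSE / nRMSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from .regression import metrics

logger = logging.getLogger(__name__)

__all__ = [
    "GroundPlane",
    "LAI_FEATURES",
    "LAIModel",
    "fit_ground_plane",
    "normalize_cloud",
    "aih_height",
    "fit_lai_model",
    "predict_lai",
]

LAI_FEATURES: tuple[str, ...] = ("RDVI", "OSAVI", "VIopt", "MNLI", "SAVI", "NDVI")

# ground-noise tolerance: normalized heights below this are dropped
MIN_NORMALIZED_HEIGHT = -0.05


@dataclass(frozen=True)
class GroundPlane:
    """Terrain model z = a x + b y + c fitted to ground-classified points."""

    a: float
    b: float
    c: float

    def elevation(self, x, y):
        return self.a * np.asarray(x) + self.b * np.asarray(y) + self.c


def fit_ground_plane(points: np.ndarray) -> GroundPlane:
    """Least-squares plane through ground-classified (x, y, z) points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("need >= 3 (x, y, z) ground points")
    A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    coef, *_ = np.linalg.lstsq(A, pts[:, 2], rcond=None)
    return GroundPlane(float(coef[0]), float(coef[1]), float(coef[2]))


def normalize_cloud(cloud: np.ndarray, ground: GroundPlane) -> np.ndarray:
    """Ground-normalized heights z' = z - ground(x, y) for one plot's points.

    Points more than 5 cm below the ground surface are dropped (logged); the
    small negative remainder is kept so ground returns stay representable.
    """
    pts = np.asarray(cloud, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("cloud must be an (n, 3) array of x, y, z")
    z_prime = pts[:, 2] - ground.elevation(pts[:, 0], pts[:, 1])
    keep = z_prime >= MIN_NORMALIZED_HEIGHT
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d points below ground tolerance", dropped)
    return z_prime[keep]


def aih_height(heights, upper_pct: float = 95, lower_pct: float = 0) -> float:
    """Crop height as the AIH percentile difference (m).

    height = percentile(z', upper_pct) - lower boundary, linear
    interpolation. With ``lower_pct = 0`` (the default) the lower boundary
    is the ground datum itself — normalization already put the terrain at
    z' = 0, so a pure-canopy cloud still reads as its canopy height. A
    nonzero ``lower_pct`` uses that percentile of the heights instead.
    Needs at least 10 points.
    """
    arr = np.asarray(heights, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 10:
        raise ValueError(f"need >= 10 points for a stable AIH percentile, got {arr.size}")
    if not 0 <= lower_pct < upper_pct <= 100:
        raise ValueError("require 0 <= lower_pct < upper_pct <= 100")
    hi = np.percentile(arr, upper_pct, method="linear")
    lo = 0.0 if lower_pct == 0 else np.percentile(arr, lower_pct, method="linear")
    return float(hi - lo)


@dataclass
class LAIModel:
    """Fitted random-forest LAI inversion with its validation metrics."""

    regressor: RandomForestRegressor
    feature_names: tuple[str, ...]
    r2: float
    rmse: float
    nrmse_pct: float
    seed: int
    degenerate_target: bool = False


def _feature_matrix(vi_table: pd.DataFrame, names: tuple[str, ...]) -> np.ndarray:
    missing_cols = [n for n in names if n not in vi_table.columns]
    if missing_cols:
        raise ValueError(f"missing feature columns: {missing_cols}")
    X = vi_table.loc[:, list(names)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        bad = vi_table.index[~np.isfinite(X).all(axis=1)].tolist()
        raise ValueError(f"missing/non-finite feature values for plots {bad}")
    return X


def fit_lai_model(
    vi_table: pd.DataFrame,
    lai_obs,
    seed: int,
    *,
    n_estimators: int = 500,
    max_depth: int | None = None,
    validation_fraction: float = 0.25,
) -> LAIModel:
    """Train the six-VI random-forest LAI inversion model.

    Requires >= 30 samples and complete features. A random
    ``validation_fraction`` is held out for the reported R^2 / RMSE / nRMSE;
    the returned regressor is then refitted on all samples. A constant
    observed LAI makes R^2 undefined and flags the model degenerate.
    """
    y = np.asarray(lai_obs, dtype=float)
    if len(y) != len(vi_table):
        raise ValueError("lai_obs length does not match vi_table rows")
    if len(y) < 30:
        raise ValueError(f"need >= 30 samples, got {len(y)}")
    X = _feature_matrix(vi_table, LAI_FEATURES)
    rf = RandomForestRegressor(
        n_estimators=n_estimators, max_depth=max_depth, random_state=seed
    )
    if np.ptp(y) == 0.0:
        logger.warning("constant observed LAI: R^2 undefined")
        rf.fit(X, y)
        return LAIModel(rf, LAI_FEATURES, float("nan"), 0.0, 0.0, seed, True)
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=validation_fraction, random_state=seed
    )
    rf.fit(X_tr, y_tr)
    r2, rmse, nrmse = metrics(y_val, rf.predict(X_val))
    rf.fit(X, y)
    return LAIModel(rf, LAI_FEATURES, r2, rmse, nrmse, seed)


def predict_lai(model: LAIModel, vi_table: pd.DataFrame) -> np.ndarray:
    """Non-negative LAI predictions; features are aligned by column name."""
    X = _feature_matrix(vi_table, model.feature_names)
    return np.maximum(model.regressor.predict(X), 0.0)
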