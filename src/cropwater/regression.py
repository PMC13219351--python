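"""Multimodal machine-learning regression of plant moisture content.

Five feature combinations (VIs, ET, VIs+ET, VIs+TIs, VIs+TIs+ET) are paired
with four regressors (PLSR, BPNN, SVR, RFR) under seeded k-fold
cross-validation. The spectral block is the six moisture-sensitive indices
selected by cross-stage Pearson screening (NGI, CI_G, VSWI, NDWI, MRETVI,
NLI); the thermal block is (delta_T, CWSI); the ET block is stage-cumulative
crop evapotranspiration by default.

Hyperparameters are tuned by a seeded random search on inner folds (PLSR
components, BPNN hidden width, RFR trees / max features); SVR is not
searched — it runs an RBF kernel with C = 1.0 and gamma = 1/n_features.
Accuracy is reported on pooled out-of-fold predictions with

    R^2 = 1 - sum((x_i - y_i)^2) / sum((x_i - x_bar)^2)
    RMSE = sqrt(mean((x_i - y_i)^2)),   nRMSE = RMSE / x_bar * 100%

where x are measured and y predicted values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

logger = logging.getLogger(__name__)

__all__ = [
    "VI_FEATURES",
    "TI_FEATURES",
    "ET_FEATURE",
    "COMBOS",
    "ALGORITHMS",
    "FeatureSet",
    "CVResult",
    "metrics",
    "assemble_features",
    "train_eval",
    "run_matrix",
]

VI_FEATURES: tuple[str, ...] = ("NGI", "CI_G", "VSWI", "NDWI", "MRETVI", "NLI")
TI_FEATURES: tuple[str, ...] = ("delta_t", "cwsi")
ET_FEATURE: str = "etc_cum"

COMBOS: dict[str, tuple[str, ...]] = {
    "VIs": VI_FEATURES,
    "ET": (ET_FEATURE,),
    "VIs+ET": VI_FEATURES + (ET_FEATURE,),
    "VIs+TIs": VI_FEATURES + TI_FEATURES,
    "VIs+TIs+ET": VI_FEATURES + TI_FEATURES + (ET_FEATURE,),
}

ALGORITHMS: tuple[str, ...] = ("PLSR", "BPNN", "SVR", "RFR")


@dataclass(frozen=True)
class FeatureSet:
    """One combo's complete plot x feature matrix."""

    combo: str
    matrix: pd.DataFrame          # index = plot ids, columns = feature names
    dropped_plots: tuple = ()
    keep_rows: tuple = ()         # positional indices of retained input rows

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.matrix.columns)


@dataclass(frozen=True)
class CVResult:
    """Pooled cross-validation accuracy for one algorithm x combo cell."""

    algorithm: str
    combo: str
    r2: float
    rmse: float
    nrmse_pct: float
    fold_r2: tuple[float, ...]
    best_params: dict
    seed: int
    stage: str | None = None


def metrics(observed, predicted) -> tuple[float, float, float]:
    """(R^2, RMSE, nRMSE %) with the observed mean as the normalizer.

    A zero-variance observed vector makes R^2 undefined (NaN, flagged in the
    log); a zero observed mean makes nRMSE undefined.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("observed and predicted must be equal-length, non-empty")
    ss_res = float(np.sum((x - y) ** 2))
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    if ss_tot == 0.0:
        logger.warning("zero-variance observations: R^2 undefined")
        r2 = float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    xbar = float(x.mean())
    nrmse = rmse / xbar * 100.0 if xbar != 0.0 else float("nan")
    return r2, rmse, nrmse


def assemble_features(observations: pd.DataFrame, combo: str) -> FeatureSet:
    """Extract one combo's columns from the per-plot observation table.

    Rows with a missing value in any required column are dropped and their
    plot ids logged; columns outside the combo are ignored entirely.
    """
    if combo not in COMBOS:
        raise ValueError(f"unknown combo {combo!r}; choose from {sorted(COMBOS)}")
    cols = list(COMBOS[combo])
    missing_cols = [c for c in cols if c not in observations.columns]
    if missing_cols:
        raise ValueError(f"observations lack columns {missing_cols} for combo {combo!r}")
    mat = observations.loc[:, cols].apply(pd.to_numeric, errors="coerce")
    if "plot_id" in observations.columns:
        mat.index = observations["plot_id"].to_numpy()
    keep = np.isfinite(mat.to_numpy(dtype=float)).all(axis=1)
    dropped = tuple(mat.index[~keep])
    if dropped:
        logger.warning("combo %s: dropped plots with missing values: %s", combo, dropped)
    return FeatureSet(combo, mat.loc[keep], dropped, tuple(np.flatnonzero(keep)))


def _make_estimator(algorithm: str, params: dict, n_features: int, seed: int):
    if algorithm == "PLSR":
        est = PLSRegression(n_components=params.get("n_components", 2))
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if algorithm == "BPNN":
        est = MLPRegressor(
            hidden_layer_sizes=(params.get("hidden", 32),),
            activation="relu",
            solver="adam",
            max_iter=2000,
            random_state=seed,
        )
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if algorithm == "SVR":
        # fixed configuration, deliberately not searched
        est = SVR(kernel="rbf", C=1.0, gamma=1.0 / n_features)
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if algorithm == "RFR":
        return RandomForestRegressor(
            n_estimators=params.get("n_estimators", 300),
            max_features=params.get("max_features", 1.0),
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _sample_params(algorithm: str, n_features: int, rng: np.random.Generator) -> dict:
    if algorithm == "PLSR":
        return {"n_components": int(rng.integers(1, min(9, n_features) + 1))}
    if algorithm == "BPNN":
        return {"hidden": int(rng.integers(4, 129))}
    if algorithm == "RFR":
        return {
            "n_estimators": int(rng.integers(100, 801)),
            "max_features": int(rng.integers(1, n_features + 1)),
        }
    return {}


def _search_params(
    algorithm: str,
    X: np.ndarray,
    y: np.ndarray,
    budget: int,
    seed: int,
    inner_folds: int = 3,
) -> dict:
    """Seeded random search scored by inner-fold pooled RMSE."""
    if algorithm == "SVR" or budget <= 0:
        return {}
    rng = np.random.default_rng(seed)
    n_features = X.shape[1]
    candidates = [_sample_params(algorithm, n_features, rng) for _ in range(budget)]
    # dedupe while keeping draw order
    seen, unique = set(), []
    for c in candidates:
        key = tuple(sorted(c.items()))
        if key not in seen:
            seen.add(key)
            unique.append(c)
    inner = KFold(n_splits=min(inner_folds, len(y)), shuffle=True, random_state=seed)
    best, best_rmse = {}, np.inf
    for params in unique:
        preds = np.empty_like(y)
        try:
            for tr, te in inner.split(X):
                est = _make_estimator(algorithm, params, n_features, seed)
                est.fit(X[tr], y[tr])
                preds[te] = np.ravel(est.predict(X[te]))
        except ValueError:
            continue  # e.g. n_components > rank on a small fold
        rmse = float(np.sqrt(np.mean((y - preds) ** 2)))
        if rmse < best_rmse:
            best, best_rmse = params, rmse
    return best


def train_eval(
    features: FeatureSet,
    pmc,
    algorithm: str,
    n_folds: int = 5,
    search_budget: int = 50,
    seed: int = 0,
    stage: str | None = None,
) -> CVResult:
    """Seeded k-fold cross-validation of one algorithm on one combo.

    Hyperparameters are tuned once on the full matrix with an inner-fold
    random search, then each outer training fold fits a fresh estimator and
    predicts its held-out fold; metrics pool the out-of-fold predictions.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    X = features.matrix.to_numpy(dtype=float)
    y = np.asarray(pmc, dtype=float)
    if len(y) != len(X):
        raise ValueError("pmc length does not match feature rows")
    if n_folds > len(y):
        raise ValueError(f"n_folds={n_folds} exceeds {len(y)} samples")
    if len(y) // n_folds < 2:
        raise ValueError("need >= 2 samples per fold")
    params = _search_params(algorithm, X, y, search_budget, seed)
    outer = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    preds = np.empty_like(y)
    fold_r2 = []
    for tr, te in outer.split(X):
        est = _make_estimator(algorithm, params, X.shape[1], seed)
        est.fit(X[tr], y[tr])
        preds[te] = np.ravel(est.predict(X[te]))
        fold_r2.append(metrics(y[te], preds[te])[0])
    r2, rmse, nrmse = metrics(y, preds)
    return CVResult(algorithm, features.combo, r2, rmse, nrmse,
                    tuple(fold_r2), params, seed, stage)


def run_matrix(
    observations: pd.DataFrame,
    stages,
    algorithms=ALGORITHMS,
    combos=tuple(COMBOS),
    seed: int = 0,
    n_folds: int = 5,
    search_budget: int = 50,
) -> pd.DataFrame:
    """One CV cell per stage x algorithm x combo, as a tidy accuracy table.

    ``observations`` must carry a ``stage`` column plus ``pmc`` and every
    feature column the requested combos need.
    """
    if "stage" not in observations.columns or "pmc" not in observations.columns:
        raise ValueError("observations need 'stage' and 'pmc' columns")
    have = set(observations["stage"])
    absent = [s for s in stages if s not in have]
    if absent:
        raise ValueError(f"observations cover no rows for stages {absent}")
    rows = []
    for stage in stages:
        obs = observations[observations["stage"] == stage]
        for algorithm in algorithms:
            for combo in combos:
                fs = assemble_features(obs, combo)
                y = obs["pmc"].to_numpy(dtype=float)[list(fs.keep_rows)]
                res = train_eval(fs, y, algorithm, n_folds=n_folds,
                                 search_budget=search_budget, seed=seed, stage=stage)
                rows.append(
                    {
                        "stage": stage,
                        "algorithm": algorithm,
                        "combo": combo,
                        "r2": res.r2,
                        "rmse": res.rmse,
                        "nrmse_pct": res.nrmse_pct,
                        "best_params": repr(res.best_params),
                        "seed": seed,
                    }
                )
    return pd.DataFrame(rows)
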