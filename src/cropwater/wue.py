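"""Plant moisture content, water use efficiency, and irrigation thresholds.

PMC is the fresh-minus-dry to fresh weight ratio of aboveground tissue, in
percent. WUE (kg dry biomass per m^3 of transpired water) follows from the
biomass-transpiration identity m_bio = WUE * integral(T_c,adj dt): with
biomass in g/m^2 and cumulative transpiration in mm (= L/m^2), the ratio of
the two is numerically WUE in kg/m^3.

Per treatment and growth stage, WUE is regressed on PMC with three
functional forms (linear, quadratic, power). A concave quadratic has an
interior maximum at PMC* = -b/(2a); that vertex, reported to one decimal,
is the stage's WUE-optimal moisture threshold and drives the irrigation
prescription: irrigate when predicted PMC falls below the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "WUEFitResult",
    "pmc",
    "wue_from_biomass",
    "fit_wue_pmc",
    "optimal_pmc_threshold",
    "prescribe",
]


@dataclass(frozen=True)
class WUEFitResult:
    """One fitted WUE = f(PMC) relation."""

    form: str                      # "linear" | "quadratic" | "power"
    coefficients: tuple[float, ...]  # (a, b) linear/power; (a, b, c) quadratic
    r2: float
    treatment: str | None = None
    stage: str | None = None

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "linear":
            b, a = self.coefficients[1], self.coefficients[0]
            return a * x + b
        if self.form == "quadratic":
            a, b, c = self.coefficients
            return a * x**2 + b * x + c
        a, b = self.coefficients
        return a * np.power(x, b)


def pmc(PFW: float, PDW: float) -> float:
    """Plant moisture content in percent: 100 (PFW - PDW) / PFW."""
    if not (PFW >= PDW > 0):
        raise ValueError(f"require PFW >= PDW > 0, got PFW={PFW}, PDW={PDW}")
    return 100.0 * (PFW - PDW) / PFW


def wue_from_biomass(m_bio: float, cum_transpiration: float) -> float:
    """WUE (kg/m^3) from biomass (g/m^2) and cumulative transpiration (mm)."""
    if cum_transpiration <= 0:
        raise ValueError("cumulative transpiration must be positive")
    return m_bio / cum_transpiration


def _r2(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def fit_wue_pmc(
    samples,
    form: str,
    treatment: str | None = None,
    stage: str | None = None,
) -> WUEFitResult:
    """Least-squares fit of WUE on PMC with one of three functional forms.

    ``samples`` is an iterable of (pmc_percent, wue) pairs. Forms:
    linear y = a x + b (>=3 points), quadratic y = a x^2 + b x + c
    (>=4 points), power y = a x^b fit by nonlinear least squares
    initialized from the log-log regression (>=3 points, positive x and y).
    """
    pts = np.asarray(list(samples), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("samples must be (pmc, wue) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if form == "linear":
        if len(x) < 3:
            raise ValueError("linear fit needs >= 3 points")
        coef = np.polyfit(x, y, 1)
        fitted = np.polyval(coef, x)
        return WUEFitResult("linear", (float(coef[0]), float(coef[1])),
                            _r2(y, fitted), treatment, stage)
    if form == "quadratic":
        if len(x) < 4:
            raise ValueError("quadratic fit needs >= 4 points")
        coef = np.polyfit(x, y, 2)
        fitted = np.polyval(coef, x)
        return WUEFitResult("quadratic",
                            (float(coef[0]), float(coef[1]), float(coef[2])),
                            _r2(y, fitted), treatment, stage)
    if form == "power":
        if len(x) < 3:
            raise ValueError("power fit needs >= 3 points")
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("power fit needs positive x and y")
        slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
        p0 = (float(np.exp(intercept)), float(slope))
        popt, _ = curve_fit(lambda t, a, b: a * np.power(t, b), x, y,
                            p0=p0, maxfev=20000)
        fitted = popt[0] * np.power(x, popt[1])
        return WUEFitResult("power", (float(popt[0]), float(popt[1])),
                            _r2(y, fitted), treatment, stage)
    raise ValueError(f"unknown form {form!r}")


def optimal_pmc_threshold(fit: WUEFitResult, pmc_domain: tuple[float, float]) -> float:
    """WUE-maximizing PMC (%) of a quadratic fit over ``pmc_domain``.

    Concave (a < 0) with an interior vertex -b/(2a): the vertex, to one
    decimal. Concave with the vertex outside the domain: the nearest domain
    endpoint (flagged in the log). Convex (a >= 0): the better of the two
    endpoints, flagged as a non-interior optimum.
    """
    if fit.form != "quadratic":
        raise ValueError("threshold extraction requires a quadratic fit")
    lo, hi = pmc_domain
    if not lo < hi:
        raise ValueError("empty PMC domain")
    a, b, _ = fit.coefficients
    if a < 0:
        vertex = -b / (2.0 * a)
        if lo <= vertex <= hi:
            return round(vertex, 1)
        clipped = lo if vertex < lo else hi
        logger.warning("vertex %.1f outside domain [%.1f, %.1f]; clipped", vertex, lo, hi)
        return round(clipped, 1)
    logger.warning("convex quadratic (a=%.4g >= 0): boundary maximum reported", a)
    best = max((lo, hi), key=lambda v: fit.predict(v))
    return round(float(best), 1)


def prescribe(
    stage_thresholds: dict[str, float],
    predicted_pmc: pd.DataFrame,
    deadband: float = 0.0,
) -> pd.DataFrame:
    """Per-plot irrigation actions from predicted PMC vs stage thresholds.

    ``predicted_pmc`` needs columns plot_id, stage, pmc_pct. Action is
    "irrigate" when predicted PMC < threshold - deadband, else "hold"
    (boundary holds). Raises if a stage lacks a threshold.
    """
    required = {"plot_id", "stage", "pmc_pct"}
    if not required.issubset(predicted_pmc.columns):
        raise ValueError(f"predicted_pmc must have columns {sorted(required)}")
    missing = set(predicted_pmc["stage"]) - set(stage_thresholds)
    if missing:
        raise ValueError(f"no threshold for stages: {sorted(missing)}")
    rows = []
    for rec in predicted_pmc.itertuples(index=False):
        thr = stage_thresholds[rec.stage]
        action = "irrigate" if rec.pmc_pct < thr - deadband else "hold"
        rows.append(
            {
                "plot_id": rec.plot_id,
                "stage": rec.stage,
                "predicted_pmc": rec.pmc_pct,
                "threshold": thr,
                "action": action,
                "rationale": f"WUE-optimal PMC threshold {thr:.1f}% for {rec.stage}",
            }
        )
    return pd.DataFrame(rows)
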