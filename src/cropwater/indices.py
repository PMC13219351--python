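"""Vegetation indices from four-band (G, R, RE, NIR) reflectance.

Eighteen indices spanning the NDVI family, soil-adjusted forms, red-edge
chlorophyll ratios and the water-sensitive NDWI/VSWI. VSWI additionally
needs the plot canopy temperature (``Ts / NDVI``). Undefined values (zero
denominators, missing Ts) propagate as NaN rather than raising, so bare-soil
plots survive a whole-scene run; correlations later exclude them pairwise.

Two printed-formula dialects are handled explicitly:

* RDVI defaults to the canonical renormalized form (NIR-R)/sqrt(NIR+R); an
  ``rdvi_as_printed`` flag reproduces the (NIR-R)/(NIR+R) variant, which is
  redundant with NDVI.
* MRETVI is 1.2*[1.2*(NIR-G) - 2.5*(RE-G)], the minimal balanced reading of
  its bracketed source formula.

CI_G / CI_RE also appear under their long aliases (green chlorophyll index,
chlorophyll index red edge); kNDVI uses tanh(((NIR-R)/(2*sigma))^2) with
sigma = 0.5*(NIR+R).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["BandReflectance", "VI_NAMES", "compute_vi", "compute_all", "select_features"]


@dataclass(frozen=True)
class BandReflectance:
    """Reflectance fractions in the four multispectral bands."""

    G: float
    R: float
    RE: float
    NIR: float

    def __post_init__(self) -> None:
        for name in ("G", "R", "RE", "NIR"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"band {name}={v} outside [0, 1]")


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0.0 else float("nan")


def _ndvi(b: BandReflectance) -> float:
    return _safe_div(b.NIR - b.R, b.NIR + b.R)


def _kndvi(b: BandReflectance) -> float:
    sigma = 0.5 * (b.NIR + b.R)
    if sigma == 0.0:
        return float("nan")
    return math.tanh(((b.NIR - b.R) / (2.0 * sigma)) ** 2)


def _rdvi(b: BandReflectance) -> float:
    return _safe_div(b.NIR - b.R, math.sqrt(b.NIR + b.R)) if b.NIR + b.R > 0 else float("nan")


def _mnli(b: BandReflectance) -> float:
    return _safe_div(1.5 * (b.NIR**2 - b.R), b.NIR**2 + b.R + 0.5)


def _osavi(b: BandReflectance) -> float:
    return 1.16 * _safe_div(b.NIR - b.R, b.NIR + b.R + 0.16)


def _nli(b: BandReflectance) -> float:
    return _safe_div(b.NIR**2 - b.R, b.NIR**2 + b.R)


def _viopt(b: BandReflectance) -> float:
    return 1.45 * _safe_div(b.NIR**2 + 1.0, b.R + 0.45)


def _ci_g(b: BandReflectance) -> float:
    return _safe_div(b.NIR, b.G) - 1.0 if b.G != 0 else float("nan")


def _ci_re(b: BandReflectance) -> float:
    return _safe_div(b.NIR, b.RE) - 1.0 if b.RE != 0 else float("nan")


def _mretvi(b: BandReflectance) -> float:
    return 1.2 * (1.2 * (b.NIR - b.G) - 2.5 * (b.RE - b.G))


def _ngi(b: BandReflectance) -> float:
    return _safe_div(b.G, b.NIR + b.G + b.RE)


def _rervi(b: BandReflectance) -> float:
    return _safe_div(b.NIR, b.RE)


def _ndwi(b: BandReflectance) -> float:
    return _safe_div(b.G - b.NIR, b.G + b.NIR)


def _dvi(b: BandReflectance) -> float:
    return b.NIR - b.R


def _savi(b: BandReflectance, l: float = 0.5) -> float:
    return _safe_div((b.NIR - b.R) * (1.0 + l), b.NIR + b.R + l)


def _msavi2(b: BandReflectance) -> float:
    disc = (2.0 * b.NIR + 1.0) ** 2 - 8.0 * (b.NIR - b.R)
    if disc < 0:
        return float("nan")
    return (2.0 * b.NIR + 1.0 - math.sqrt(disc)) / 2.0


_BAND_FORMULAS = {
    "NDVI": _ndvi,
    "kNDVI": _kndvi,
    "RDVI": _rdvi,
    "MNLI": _mnli,
    "OSAVI": _osavi,
    "NLI": _nli,
    "VIopt": _viopt,
    "CI_G": _ci_g,
    "CI_rededge": _ci_re,
    "MRETVI": _mretvi,
    "CI_RE": _ci_re,
    "NGI": _ngi,
    "RERVI": _rervi,
    "NDWI": _ndwi,
    "DVI": _dvi,
    "SAVI": _savi,
    "MSAVI2": _msavi2,
}

VI_NAMES: tuple[str, ...] = tuple(_BAND_FORMULAS) + ("VSWI",)


def compute_vi(
    name: str,
    bands: BandReflectance,
    ts: float | None = None,
    *,
    rdvi_as_printed: bool = False,
) -> float:
    """One vegetation index by name; NaN on an undefined denominator.

    ``ts`` (plot canopy temperature, deg C) is required for VSWI only.
    """
    if name == "VSWI":
        if ts is None:
            raise ValueError("VSWI requires the plot canopy temperature ts")
        ndvi = _ndvi(bands)
        return _safe_div(ts, ndvi) if not math.isnan(ndvi) else float("nan")
    if name == "RDVI" and rdvi_as_printed:
        return _ndvi(bands)
    try:
        return float(_BAND_FORMULAS[name](bands))
    except KeyError:
        raise ValueError(f"unknown vegetation index {name!r}") from None


def compute_all(
    bands: BandReflectance,
    ts: float | None = None,
    *,
    rdvi_as_printed: bool = False,
) -> dict[str, float]:
    """All indices as a name -> value map; VSWI is NaN when ``ts`` is absent."""
    out = {
        name: compute_vi(name, bands, rdvi_as_printed=rdvi_as_printed)
        for name in _BAND_FORMULAS
    }
    out["VSWI"] = compute_vi("VSWI", bands, ts) if ts is not None else float("nan")
    return out


def _abs_pearson(x: np.ndarray, y: np.ndarray, col: str) -> float:
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 2 or np.std(x[mask]) == 0.0 or np.std(y[mask]) == 0.0:
        logger.warning("feature %s: constant or empty column, |r| set to 0", col)
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = np.corrcoef(x[mask], y[mask])[0, 1]
    return abs(float(r)) if np.isfinite(r) else 0.0


def select_features(vi_table: pd.DataFrame, pmc, k: int, stages=None) -> list[str]:
    """Top-``k`` index names by |Pearson r| with plant moisture content.

    Rows of ``vi_table`` align with ``pmc``; NaNs are excluded pairwise.
    When ``stages`` (labels aligned with the rows) is given, |r| is computed
    within each stage and averaged, so a feature must perform well across
    the whole season to rank highly. Zero-variance columns get |r| = 0 with
    a warning. Ties break alphabetically; the result is ordered by
    decreasing score.
    """
    if k > vi_table.shape[1]:
        raise ValueError(f"k={k} exceeds the {vi_table.shape[1]} available indices")
    y = np.asarray(pmc, dtype=float)
    if len(y) != len(vi_table):
        raise ValueError("pmc length does not match vi_table rows")
    groups: list[np.ndarray]
    if stages is None:
        groups = [np.ones(len(y), dtype=bool)]
    else:
        labels = np.asarray(stages)
        if len(labels) != len(y):
            raise ValueError("stages length does not match vi_table rows")
        groups = [labels == s for s in pd.unique(labels)]
    scores: dict[str, float] = {}
    for col in vi_table.columns:
        x = vi_table[col].to_numpy(dtype=float)
        scores[col] = float(np.mean([_abs_pearson(x[g], y[g], col) for g in groups]))
    ranked = sorted(scores, key=lambda name: (-scores[name], name))
    return ranked[:k]
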