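"""Thermal water-stress indicators from canopy-temperature pixel distributions.

Per plot, the wet and dry reference temperatures are taken as low/high
percentiles (default 0.5% and 99.5%) of the in-plot canopy-temperature
pixels, and the crop water stress index is the position of the mean canopy
temperature between them:

    CWSI = (Tc - Twet) / (Tdry - Twet),  clipped to [0, 1].

Percentiles are linear-interpolation quantiles of the raw pixel values; no
histogram binning is involved, so the estimate is bin-width free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ThermalRecord", "percentile_bounds", "cwsi", "delta_t", "thermal_record"]


class InsufficientDataError(ValueError):
    """Fewer temperature pixels than the estimator needs."""


class DegenerateDistributionError(ValueError):
    """All pixels identical: wet and dry bounds coincide."""


@dataclass(frozen=True)
class ThermalRecord:
    plot_id: str
    t_canopy_mean: float
    t_wet: float
    t_dry: float
    delta_t: float
    cwsi: float
    degenerate: bool = False


def percentile_bounds(
    temps, p_wet: float = 0.5, p_dry: float = 99.5
) -> tuple[float, float]:
    """Wet/dry reference temperatures as percentiles of the pixel values.

    Returns ``(t_wet, t_dry)`` using linear interpolation. Requires at least
    two finite values and ``0 <= p_wet < p_dry <= 100``. Identical values
    yield a degenerate pair ``t_wet == t_dry`` (flagged by the caller).
    """
    if not 0 <= p_wet < p_dry <= 100:
        raise ValueError(f"require 0 <= p_wet < p_dry <= 100, got ({p_wet}, {p_dry})")
    arr = np.asarray(temps, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise InsufficientDataError(
            f"need >= 2 finite temperatures, got {arr.size}"
        )
    t_wet, t_dry = np.percentile(arr, [p_wet, p_dry], method="linear")
    return float(t_wet), float(t_dry)


def cwsi(t_c: float, t_wet: float, t_dry: float) -> float:
    """Crop water stress index, clipped to [0, 1]."""
    if t_dry == t_wet:
        raise DegenerateDistributionError("t_dry == t_wet: CWSI undefined")
    if t_dry < t_wet:
        raise ValueError("require t_dry > t_wet")
    return float(np.clip((t_c - t_wet) / (t_dry - t_wet), 0.0, 1.0))


def delta_t(t_c: float, t_a: float) -> float:
    """Canopy-minus-air temperature difference (deg C); negative = cooler canopy."""
    if not (np.isfinite(t_c) and np.isfinite(t_a)):
        raise ValueError("temperatures must be finite")
    return float(t_c - t_a)


def thermal_record(
    plot_id: str,
    temps,
    t_air: float,
    p_wet: float = 0.5,
    p_dry: float = 99.5,
) -> ThermalRecord:
    """Assemble the per-plot thermal indicators from raw pixels.

    Degenerate pixel distributions (all values equal) give CWSI = 0 with the
    ``degenerate`` flag set instead of raising, so whole-scene runs survive
    constant-temperature plots.
    """
    t_wet, t_dry = percentile_bounds(temps, p_wet, p_dry)
    arr = np.asarray(temps, dtype=float)
    t_mean = float(np.nanmean(arr))
    if t_dry == t_wet:
        logger.warning("plot %s: degenerate canopy-temperature distribution", plot_id)
        return ThermalRecord(plot_id, t_mean, t_wet, t_dry, t_mean - t_air, 0.0, True)
    return ThermalRecord(
        plot_id, t_mean, t_wet, t_dry, delta_t(t_mean, t_air), cwsi(t_mean, t_wet, t_dry)
    )
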