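"""FAO-56 dual-crop-coefficient evapotranspiration with UAV-derived dynamics.

Daily crop evapotranspiration is decomposed as

    ETc = (Ks * Kcb + Ke) * ET0

where ``ET0`` is Penman-Monteith reference evapotranspiration, ``Kcb`` the
basal (transpiration) crop coefficient, ``Ks`` a water-stress multiplier and
``Ke`` the soil-evaporation coefficient.  The static tabulated ``Kcb`` of the
classic method is replaced by a dynamic chain driven by remotely sensed crop
state: the tabulated value is first adjusted for local wind and humidity,
then scaled by canopy density through LAI, and the stress factor is taken
from the thermal crop water stress index as ``Ks = 1 - CWSI``.

Ks enters the product exactly once: the stressed basal coefficient
``Ks * Kcb_a`` is what feeds the soil-evaporation terms (Kc_max, fc, Ke) and
the final ETc.  Applying it both inside Kcb and again in ETc would square the
stress response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "WeatherRecord",
    "CropState",
    "SoilEvapState",
    "ETComponents",
    "penman_monteith_et0",
    "adjust_kcb_climate",
    "scale_kcb_lai",
    "ks_from_cwsi",
    "kc_max",
    "fraction_cover",
    "exposed_wetted_fraction",
    "kr_two_stage",
    "soil_evap_coefficient",
    "daily_etc",
    "cumulate_et",
    "saturation_vapor_pressure",
    "svp_slope",
    "psychrometric_constant",
    "STATIC_KCB",
]

# Static basal crop coefficients for winter wheat (initial / mid-season
# jointing-heading / late harvest), used by the static comparison mode.
STATIC_KCB = {"initial": 0.25, "jointing": 1.15, "heading": 1.15, "grain_filling": 1.15, "late": 0.30}

# Climate adjustment of the tabulated Kcb is skipped below this value.
KCB_ADJUST_FLOOR = 0.45


def saturation_vapor_pressure(t_c: float) -> float:
    """Saturation vapor pressure (kPa) at air temperature ``t_c`` (deg C)."""
    return 0.6108 * math.exp(17.27 * t_c / (t_c + 237.3))


def svp_slope(t_c: float) -> float:
    """Slope of the saturation vapor-pressure curve (kPa / deg C)."""
    return 4098.0 * saturation_vapor_pressure(t_c) / (t_c + 237.3) ** 2


def psychrometric_constant(pressure_kpa: float = 101.3) -> float:
    """Psychrometric constant gamma (kPa / deg C) at atmospheric pressure."""
    return 0.000665 * pressure_kpa


@dataclass(frozen=True)
class WeatherRecord:
    """One day of meteorology, units as in the daily Penman-Monteith form."""

    date: str
    T: float          # daily mean air temperature, deg C
    u2: float         # wind speed at 2 m, m/s
    RH_min: float     # daily minimum relative humidity, %
    Rn: float         # net radiation, MJ m-2 d-1
    G: float          # soil heat flux, MJ m-2 d-1
    es: float         # saturation vapor pressure, kPa
    ea: float         # actual vapor pressure, kPa
    Delta: float = float("nan")   # slope of svp curve, kPa/degC (derived if NaN)
    gamma: float = float("nan")   # psychrometric constant, kPa/degC (derived if NaN)

    def __post_init__(self) -> None:
        if not (self.es >= self.ea > 0):
            raise ValueError(
                f"vapor pressures must satisfy es >= ea > 0, got es={self.es}, ea={self.ea}"
            )
        if math.isnan(self.Delta):
            object.__setattr__(self, "Delta", svp_slope(self.T))
        if math.isnan(self.gamma):
            object.__setattr__(self, "gamma", psychrometric_constant())
        if self.Delta <= 0 or self.gamma <= 0:
            raise ValueError("Delta and gamma must be positive")


@dataclass
class CropState:
    """Per-plot crop condition on a given day."""

    stage: str
    Kcb_tab: float           # tabulated basal crop coefficient for the stage
    h: float                 # plant height, m
    h_max: float             # stage maximum plant height, m
    LAI: float
    CWSI: float
    k: float = 0.7           # canopy attenuation coefficient
    Kc_min: float = 0.15     # bare-soil minimum crop coefficient (0.15-0.20)

    def __post_init__(self) -> None:
        if not 0.0 <= self.CWSI <= 1.0:
            raise ValueError(f"CWSI must be in [0, 1], got {self.CWSI}")
        if self.h <= 0 or self.h_max <= 0:
            raise ValueError("plant height must be positive")
        if self.LAI < 0:
            raise ValueError("LAI must be non-negative")
        if not 0.15 <= self.Kc_min <= 0.20:
            raise ValueError("Kc_min outside the documented 0.15-0.20 range")


@dataclass
class SoilEvapState:
    """Surface-layer evaporation bookkeeping (mm), mutated day by day."""

    De: float = 0.0          # cumulative evaporation depth since last wetting
    REW: float = 8.0         # readily evaporable water (sandy loam default)
    TEW: float = 22.0        # total evaporable water (sandy loam default)
    fw: float = 1.0          # wetted-soil fraction (sprinkler wets everything)

    def __post_init__(self) -> None:
        if not 0 < self.REW < self.TEW:
            raise ValueError("require 0 < REW < TEW")
        if not 0 <= self.De <= self.TEW:
            raise ValueError("require 0 <= De <= TEW")
        if not 0 < self.fw <= 1:
            raise ValueError("require fw in (0, 1]")


@dataclass(frozen=True)
class ETComponents:
    """Every intermediate of the daily dual-Kc chain plus the day's ETc."""

    ET0: float
    Kcb_adjust: float
    Kcb_a: float
    Ks: float
    Kc_max: float
    fc: float
    few: float
    Kr: float
    Ke: float
    ETc: float
    ETc_cum: float = float("nan")


def penman_monteith_et0(w: WeatherRecord) -> float:
    """Daily reference evapotranspiration ET0 (mm/d), floored at zero.

    ET0 = [0.408 Delta (Rn - G) + gamma 900/(T+273) u2 (es - ea)]
          / [Delta + gamma (1 + 0.34 u2)]
    """
    num = 0.408 * w.Delta * (w.Rn - w.G) + w.gamma * (900.0 / (w.T + 273.0)) * w.u2 * (w.es - w.ea)
    den = w.Delta + w.gamma * (1.0 + 0.34 * w.u2)
    return max(num / den, 0.0)


def adjust_kcb_climate(Kcb_tab: float, h: float, u2: float, RH_min: float) -> float:
    """Adjust the tabulated basal coefficient for local wind and humidity.

    Kcb_adjust = Kcb_tab + (h/3)^0.3 [0.04 (u2 - 2) - 0.004 (RH_min - 45)]

    Tabulated values below 0.45 are returned unchanged: for sparse canopies
    the climatic correction is not applied.
    """
    if h <= 0:
        raise ValueError("plant height must be positive")
    if Kcb_tab < KCB_ADJUST_FLOOR:
        return Kcb_tab
    return Kcb_tab + (h / 3.0) ** 0.3 * (0.04 * (u2 - 2.0) - 0.004 * (RH_min - 45.0))


def scale_kcb_lai(Kcb_adjust: float, LAI: float, k: float = 0.7, Kc_min: float = 0.15) -> float:
    """Scale the adjusted basal coefficient by canopy density.

    Kcb_a = Kc_min + (Kcb_adjust - Kc_min) [1 - exp(-k LAI)]

    Rises from Kc_min on bare soil to Kcb_adjust for a closed canopy.
    """
    if LAI < 0:
        raise ValueError("LAI must be non-negative")
    if Kcb_adjust < Kc_min:
        raise ValueError(f"Kcb_adjust ({Kcb_adjust}) below Kc_min ({Kc_min})")
    return Kc_min + (Kcb_adjust - Kc_min) * (1.0 - math.exp(-k * LAI))


def ks_from_cwsi(cwsi: float) -> float:
    """Water-stress coefficient from the thermal stress index: Ks = 1 - CWSI."""
    if not 0.0 <= cwsi <= 1.0:
        raise ValueError(f"CWSI must lie in [0, 1], got {cwsi}")
    return 1.0 - cwsi


def kc_max(Kcb_tab: float, Kcb: float, u2: float, RH_min: float, h_max: float) -> float:
    """Upper bound on Kc after a wetting event.

    Kc_max = max{ Kcb_tab + [0.04 (u2-2) - 0.004 (RH_min-45)] (h_max/3)^0.3,
                  Kcb + 0.05 }
    """
    if h_max <= 0:
        raise ValueError("h_max must be positive")
    climate_term = Kcb_tab + (0.04 * (u2 - 2.0) - 0.004 * (RH_min - 45.0)) * (h_max / 3.0) ** 0.3
    return max(climate_term, Kcb + 0.05)


def fraction_cover(Kcb: float, Kc_min: float, Kc_max: float, h: float) -> float:
    """Canopy cover fraction from the coefficient chain.

    fc = [(Kcb - Kc_min)/(Kc_max - Kc_min)]^(1 + 0.5 h), clipped to [0, 0.99].
    """
    if Kc_max <= Kc_min:
        raise ValueError("require Kc_max > Kc_min")
    base = (Kcb - Kc_min) / (Kc_max - Kc_min)
    base = min(max(base, 0.0), 1.0)
    return min(base ** (1.0 + 0.5 * h), 0.99)


def exposed_wetted_fraction(fc: float, fw: float) -> float:
    """Fraction of soil both exposed and wetted: few = min(1 - fc, fw)."""
    return min(1.0 - fc, fw)


def kr_two_stage(De: float, REW: float, TEW: float) -> float:
    """Two-stage soil-evaporation reduction coefficient.

    Stage 1 (energy limited, De <= REW): Kr = 1.  Stage 2 (falling rate):
    Kr = (TEW - De)/(TEW - REW), floored at 0.
    """
    if TEW <= REW:
        raise ValueError("require TEW > REW")
    if De <= REW:
        return 1.0
    return max((TEW - De) / (TEW - REW), 0.0)


def soil_evap_coefficient(Kr: float, Kc_max: float, Kcb: float, few: float) -> float:
    """Soil evaporation coefficient Ke = Kr (Kc_max - Kcb), capped at few*Kc_max."""
    return max(min(Kr * (Kc_max - Kcb), few * Kc_max), 0.0)


def daily_etc(
    w: WeatherRecord,
    crop: CropState,
    soil: SoilEvapState,
    *,
    static_kcb: bool = False,
) -> ETComponents:
    """One day of the dual-Kc chain; mutates ``soil.De`` for the next call.

    The chain: ET0 -> climate-adjusted Kcb -> LAI-scaled Kcb_a -> Ks from
    CWSI -> stressed basal Ks*Kcb_a -> Kc_max, fc, few, Kr -> Ke ->
    ETc = (Ks*Kcb_a + Ke) * ET0.  With ``static_kcb`` the tabulated stage
    value is used directly (no climate/LAI dynamics), for comparison runs.
    """
    et0 = penman_monteith_et0(w)
    if static_kcb:
        kcb_adjust = crop.Kcb_tab
        kcb_a = crop.Kcb_tab
    else:
        kcb_adjust = adjust_kcb_climate(crop.Kcb_tab, crop.h, w.u2, w.RH_min)
        kcb_a = scale_kcb_lai(kcb_adjust, crop.LAI, crop.k, crop.Kc_min)
    ks = ks_from_cwsi(crop.CWSI)
    kcb_stressed = ks * kcb_a
    kcmax = kc_max(crop.Kcb_tab, kcb_stressed, w.u2, w.RH_min, crop.h_max)
    fc = fraction_cover(kcb_stressed, crop.Kc_min, kcmax, crop.h)
    few = exposed_wetted_fraction(fc, soil.fw)
    kr = kr_two_stage(soil.De, soil.REW, soil.TEW)
    ke = soil_evap_coefficient(kr, kcmax, kcb_stressed, few)
    etc = max((kcb_stressed + ke) * et0, 0.0)
    # advance the surface-layer water balance by today's evaporation depth
    soil.De = min(soil.De + ke * et0, soil.TEW)
    return ETComponents(
        ET0=et0, Kcb_adjust=kcb_adjust, Kcb_a=kcb_a, Ks=ks, Kc_max=kcmax,
        fc=fc, few=few, Kr=kr, Ke=ke, ETc=etc,
    )


def cumulate_et(daily: Sequence[ETComponents]) -> float:
    """Sum of daily ETc over the sequence (mm)."""
    if not daily:
        raise ValueError("empty ET sequence")
    return float(sum(d.ETc for d in daily))


def run_season(
    weather: Iterable[WeatherRecord],
    crop: CropState,
    soil: SoilEvapState,
    *,
    wetting_dates: frozenset[str] | set[str] = frozenset(),
    static_kcb: bool = False,
) -> list[ETComponents]:
    """Run ``daily_etc`` over a weather series with a shared soil state.

    ``soil.De`` is reset to 0 on any date in ``wetting_dates`` (irrigation or
    rain >= 4 mm), reproducing the post-wetting spike in soil evaporation.
    Returns components with the running cumulative ETc filled in.
    """
    out: list[ETComponents] = []
    cum = 0.0
    for w in weather:
        if w.date in wetting_dates:
            soil.De = 0.0
        comp = daily_etc(w, crop, soil, static_kcb=static_kcb)
        cum += comp.ETc
        out.append(replace(comp, ETc_cum=cum))
    return out
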