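"""Crop water requirement from the FAO-56 Penman–Monteith equation.

Reference evapotranspiration for a standardized grass surface:

    ET₀ = [0.408·Δ·(Rn − G) + γ·(900/(T + 273))·u₂·(es − ea)]
          / [Δ + γ·(1 + 0.34·u₂)]            (mm/day)

with Rn net radiation and G soil heat flux (MJ m⁻² day⁻¹), T mean air
temperature at 2 m (°C), u₂ wind speed at 2 m (m s⁻¹), es/ea the saturation
and actual vapor pressures (kPa), Δ the vapor-pressure-curve slope and γ the
psychrometric constant (kPa °C⁻¹).

The crop requirement follows from a stage-dependent crop coefficient,
ET_crop = kc × ET₀, and converts to volume through the depth identity
1 mm over 1 m² = 1 L.

Δ, γ, es and ea are accepted as inputs; optional helpers compute them from
temperature, relative humidity and altitude with the standard FAO-56
auxiliary formulas, and are kept clearly separate from the main equation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "WeatherRecord",
    "CropCoefficients",
    "WaterRequirement",
    "CROP_COEFFICIENTS",
    "penman_monteith_et0",
    "kc_for_stage",
    "et_crop",
    "irrigation_volume",
    "daily_water_requirement",
    "truncate2",
    "saturation_vapor_pressure",
    "vapor_pressure_slope",
    "psychrometric_constant",
]

STAGES = ("initial", "medium", "end")


@dataclass
class WeatherRecord:
    """One day of Penman–Monteith inputs (units in the module docstring)."""

    rn: float
    g: float
    t: float
    u2: float
    es: float
    ea: float
    delta: float
    gamma: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in
                   (self.rn, self.g, self.t, self.u2, self.es, self.ea,
                    self.delta, self.gamma)):
            raise ValueError("weather inputs must be finite")
        if self.ea < 0 or self.es < self.ea:
            raise ValueError("need es ≥ ea ≥ 0")
        if self.u2 < 0:
            raise ValueError("wind speed u2 must be non-negative")
        if self.delta <= 0 or self.gamma <= 0:
            raise ValueError("delta and gamma must be positive")
        if self.t <= -273:
            raise ValueError("temperature below absolute zero")


@dataclass
class CropCoefficients:
    """Stage-wise crop coefficients and maximum plant height."""

    crop: str
    kc_initial: float
    kc_medium: float
    kc_end: float
    max_height_m: float

    def __post_init__(self) -> None:
        if min(self.kc_initial, self.kc_medium, self.kc_end) <= 0:
            raise ValueError("crop coefficients must be positive")
        if self.max_height_m <= 0:
            raise ValueError("max height must be positive")


#: Packaged crop-factor table (kc by growth stage, with max height in m).
CROP_COEFFICIENTS: dict[str, CropCoefficients] = {
    c.crop: c for c in (
        CropCoefficients("corn", 0.80, 1.15, 0.15, 1.5),
        CropCoefficients("sugar cane", 0.40, 1.25, 0.75, 3.0),
        CropCoefficients("rice", 1.05, 1.20, 0.90, 1.0),
        CropCoefficients("tomato", 0.45, 1.15, 0.80, 2.0),
        CropCoefficients("cucumber", 0.45, 0.90, 0.75, 1.5),
    )
}


def penman_monteith_et0(w: WeatherRecord) -> float:
    """FAO-56 Penman–Monteith reference evapotranspiration, mm/day.

    A negative computed value (possible when Rn < G) is clamped to zero with
    a warning: daily reference evapotranspiration is physically non-negative
    in this application.
    """
    num = 0.408 * w.delta * (w.rn - w.g) \
        + w.gamma * (900.0 / (w.t + 273.0)) * w.u2 * (w.es - w.ea)
    den = w.delta + w.gamma * (1.0 + 0.34 * w.u2)
    et0 = num / den
    if et0 < 0:
        warnings.warn(f"computed ET0 = {et0:.4f} mm/day < 0 (Rn < G); clamped to 0",
                      stacklevel=2)
        return 0.0
    return et0


def kc_for_stage(crop: str, stage: str,
                 table: dict[str, CropCoefficients] | None = None) -> float:
    """Crop coefficient for a growth stage ∈ {initial, medium, end}."""
    if table is None:
        table = CROP_COEFFICIENTS
    key = crop.strip().lower()
    if key not in table:
        raise KeyError(f"unknown crop '{crop}'; known: {sorted(table)}")
    if stage not in STAGES:
        raise KeyError(f"unknown stage '{stage}'; expected one of {STAGES}")
    c = table[key]
    return {"initial": c.kc_initial, "medium": c.kc_medium, "end": c.kc_end}[stage]


def et_crop(kc: float, et0: float) -> float:
    """Crop evapotranspiration ET_crop = kc × ET₀ (mm/day)."""
    if kc < 0 or et0 < 0:
        raise ValueError("kc and et0 must be non-negative")
    return kc * et0


def irrigation_volume(etcrop_mm_day: float, area_m2: float) -> float:
    """Daily irrigation volume in liters: depth × area (1 mm·m² = 1 L)."""
    if etcrop_mm_day < 0 or area_m2 < 0:
        raise ValueError("depth and area must be non-negative")
    return etcrop_mm_day * area_m2


def truncate2(value: float) -> float:
    """Truncate toward zero at two decimals (reporting convention)."""
    return math.trunc(value * 100.0) / 100.0


@dataclass
class WaterRequirement:
    """ET₀, crop ET and daily volume for a plot."""

    et0: float
    etcrop: float
    area_m2: float
    volume_l_day: float

    def __post_init__(self) -> None:
        if min(self.et0, self.etcrop, self.area_m2, self.volume_l_day) < 0:
            raise ValueError("water requirement fields must be non-negative")


def daily_water_requirement(crop: str, stage: str, et0: float, area_m2: float,
                            depth_decimals: int | None = 1) -> WaterRequirement:
    """End-to-end requirement: kc lookup → ET_crop → plot volume.

    ``depth_decimals`` rounds the irrigation depth (mm) before the volume
    product, matching how dosing charts quote depth to 0.1 mm (ET_crop 6.325
    → 6.3 mm → 630 L over 100 m²).  Pass ``None`` to keep full precision.
    """
    kc = kc_for_stage(crop, stage)
    etc = et_crop(kc, et0)
    depth = round(etc, depth_decimals) if depth_decimals is not None else etc
    return WaterRequirement(et0=et0, etcrop=etc, area_m2=area_m2,
                            volume_l_day=irrigation_volume(depth, area_m2))


# ---------------------------------------------------------------------------
# FAO-56 auxiliary helpers (not part of the core equation's inputs)


def saturation_vapor_pressure(t_celsius: float) -> float:
    """e°(T) = 0.6108·exp(17.27·T/(T+237.3)) kPa."""
    return 0.6108 * math.exp(17.27 * t_celsius / (t_celsius + 237.3))


def vapor_pressure_slope(t_celsius: float) -> float:
    """Δ(T) = 4098·e°(T)/(T+237.3)² kPa/°C."""
    return 4098.0 * saturation_vapor_pressure(t_celsius) / (t_celsius + 237.3) ** 2


def psychrometric_constant(altitude_m: float = 0.0) -> float:
    """γ = 0.000665·P with P = 101.3·((293 − 0.0065·z)/293)^5.26 kPa."""
    pressure = 101.3 * ((293.0 - 0.0065 * altitude_m) / 293.0) ** 5.26
    return 0.000665 * pressure


def weather_from_basic(rn: float, g: float, t: float, u2: float,
                       rh_pct: float, altitude_m: float = 0.0) -> WeatherRecord:
    """Build a WeatherRecord from temperature, relative humidity and altitude
    using the auxiliary formulas (es from T, ea = es·RH/100)."""
    es = saturation_vapor_pressure(t)
    ea = es * rh_pct / 100.0
    return WeatherRecord(rn=rn, g=g, t=t, u2=u2, es=es, ea=ea,
                         delta=vapor_pressure_slope(t),
                         gamma=psychrometric_constant(altitude_m))
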