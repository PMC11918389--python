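"""Fertilizer dosing from soil nutrient deficits.

Probe electronics report N, P, K in mg/kg of soil, while recommendation
guides dose fertilizer in kg/ha.  The two are linked through the sampled
soil layer:

    kg/ha = mg/kg × layer_thickness(cm) × bulk_density(g/cm³) / 10

The product ``thickness × density / 10`` is the *chart factor*.  Deficits are
then converted to commercial product masses using the standard nutrient
fractions: urea is 46 % N, triple super phosphate (TSP) 20 % P and muriate of
potash (MOP) 60 % K.

The packaged reference chart uses chart_factor = 0.36, the unique value that
reproduces the published dosing chart exactly (10 mg/kg → urea 7.8 kg/ha,
TSP 18 kg/ha, MOP 6 kg/ha, rows scaling linearly).  Note the tension: a
10–15 cm layer at 1.0–1.4 g/cm³ implies factors of 1.0–2.1, so custom
parameters that disagree with the chart trigger a warning rather than an
error — the conversion stays parametric, the chart stays reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ConversionParams",
    "FertilizerPlan",
    "NUTRIENT_FRACTIONS",
    "CHART_FACTOR_DEFAULT",
    "mgkg_to_kgha",
    "recommend",
    "build_chart",
]

#: Mass fraction of nutrient in each commercial product.
NUTRIENT_FRACTIONS = {"urea": 0.46, "tsp": 0.20, "mop": 0.60}

#: Nutrient addressed by each product.
PRODUCT_NUTRIENT = {"urea": "n", "tsp": "p", "mop": "k"}

#: Factor reproducing the published chart (see module docstring).
CHART_FACTOR_DEFAULT = 0.36


@dataclass
class ConversionParams:
    """Soil-layer parameters for the mg/kg → kg/ha conversion.

    Either give ``thickness_cm`` and ``bulk_density`` (chart_factor is then
    thickness × density / 10) or set ``chart_factor`` directly.
    """

    thickness_cm: float | None = None
    bulk_density: float | None = None
    chart_factor: float | None = None

    def __post_init__(self) -> None:
        if self.chart_factor is None:
            if self.thickness_cm is None and self.bulk_density is None:
                self.chart_factor = CHART_FACTOR_DEFAULT
            elif self.thickness_cm is None or self.bulk_density is None:
                raise ValueError("give both thickness_cm and bulk_density, or chart_factor")
            else:
                if self.thickness_cm <= 0 or self.bulk_density <= 0:
                    raise ValueError("thickness and density must be positive")
                self.chart_factor = self.thickness_cm * self.bulk_density / 10.0
        if not self.chart_factor > 0:
            raise ValueError("chart_factor must be positive")
        if not math.isclose(self.chart_factor, CHART_FACTOR_DEFAULT, rel_tol=1e-9):
            warnings.warn(
                f"chart_factor {self.chart_factor:g} differs from the reference "
                f"chart's {CHART_FACTOR_DEFAULT}; dosing will not match the "
                "packaged chart", stacklevel=2)


def mgkg_to_kgha(value_mgkg: float, params: ConversionParams | None = None) -> float:
    """Convert a nutrient concentration from mg/kg to kg/ha.

    kg/ha = mg/kg × thickness × density / 10 = mg/kg × chart_factor.
    """
    if params is None:
        params = ConversionParams()
    if not math.isfinite(value_mgkg):
        raise ValueError("nutrient value must be finite")
    return float(value_mgkg) * params.chart_factor


@dataclass
class FertilizerPlan:
    """Per-product dose in kg/ha; ``None`` marks a not-applicable nutrient
    (non-positive deficit)."""

    urea: float | None
    tsp: float | None
    mop: float | None

    def __post_init__(self) -> None:
        for name in ("urea", "tsp", "mop"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} dose cannot be negative")

    def as_dict(self) -> dict[str, float | str]:
        return {k: ("N/A" if getattr(self, k) is None else getattr(self, k))
                for k in ("urea", "tsp", "mop")}


def _dose(deficit_mgkg: float, product: str, factor: float) -> float | None:
    """Exact (unrounded) product dose in kg/ha, or None if no deficit."""
    if not math.isfinite(deficit_mgkg):
        raise ValueError("deficit must be finite")
    if deficit_mgkg <= 0:
        return None
    return deficit_mgkg * factor / NUTRIENT_FRACTIONS[product]


def recommend(deficits: dict[str, float],
              params: ConversionParams | None = None,
              decimals: int = 1) -> FertilizerPlan:
    """Fertilizer plan for N/P/K deficits given in mg/kg.

    Non-positive deficits map to not-applicable.  Doses are exact products of
    ``deficit × chart_factor / nutrient_fraction`` rounded to ``decimals``
    (pass ``decimals=None`` for full precision); the mapping is linear in the
    deficit before rounding.
    """
    if params is None:
        params = ConversionParams()
    out: dict[str, float | None] = {}
    for product, nutrient in PRODUCT_NUTRIENT.items():
        d = _dose(float(deficits.get(nutrient, 0.0)), product, params.chart_factor)
        if d is not None and decimals is not None:
            d = round(d, decimals)
        out[product] = d
    return FertilizerPlan(**out)


def build_chart(params: ConversionParams | None = None,
                deficit_grid: list[float] | None = None) -> pd.DataFrame:
    """Reference dosing chart over a deficit grid (default 10…100 mg/kg).

    Chart convention: the base row is computed at 10 mg/kg with urea rounded
    to one decimal and TSP/MOP to the nearest integer; other rows scale the
    rounded base linearly (so urea 7.8 at 10 mg/kg becomes exactly 78 at
    100 mg/kg).
    """
    if params is None:
        params = ConversionParams()
    if deficit_grid is None:
        deficit_grid = [10.0 * i for i in range(1, 11)]
    base = {
        "urea": round(_dose(10.0, "urea", params.chart_factor), 1),
        "tsp": round(_dose(10.0, "tsp", params.chart_factor)),
        "mop": round(_dose(10.0, "mop", params.chart_factor)),
    }
    rows = []
    for d in deficit_grid:
        if d <= 0:
            rows.append({"deficit_mgkg": d, "urea": None, "tsp": None, "mop": None})
        else:
            scale = d / 10.0
            rows.append({"deficit_mgkg": d,
                         "urea": round(base["urea"] * scale, 10),
                         "tsp": round(base["tsp"] * scale, 10),
                         "mop": round(base["mop"] * scale, 10)})
    return pd.DataFrame(rows)
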