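"""Closed-loop soil-bed simulation for exercising the irrigation controllers.

The plant is a small instrumented bed (default 175.75 cm²) split into two
valve zones of three sensed segments each, mirroring the hardware trial this
package models: one zone prepared with dried soil, the other with saturated
soil.  Moisture dynamics are first-order linear with additive noise — the
simplest plant that reproduces the qualitative sensor traces:

    m_i ← clip( m_i + gain·(allocated mL) − drying·dt + noise, 0, 100 )

Water poured onto a segment already at 100 % moisture is lost to runoff (the
clip), which is precisely how a controller that ties every valve to the
global mean wastes water on an already-wet zone.  Resistive sensors map
moisture to raw counts through a monotone-decreasing affine calibration
(dry-high) with Gaussian read noise.

The loop is sense → decide → actuate at a fixed control interval, drawing
water from a finite tank; runs are seeded and reproducible, and the module
also hosts the synthetic fixture generators (sensor traces, multiband
scenes, weather series) used across the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .irrigation_control import (
    FULL_OPEN_STEPS,
    AvgControllerConfig,
    FlowCalibration,
    FuzzyConfig,
    IrrigationLedger,
    SensorFrame,
    ValveCommand,
    average_decide,
    compare_runs,
    fuzzy_decide,
)
from .raster_land import BandStack
from .water_requirement import (
    psychrometric_constant,
    saturation_vapor_pressure,
    vapor_pressure_slope,
)

__all__ = [
    "SoilBedConfig",
    "BedState",
    "SimResult",
    "step",
    "run_experiment",
    "compare_controllers",
    "generate_sensor_trace",
    "generate_scene",
    "generate_weather",
]


@dataclass
class SoilBedConfig:
    """Plant, sensing and actuation constants for one simulated bed.

    Defaults encode the reference trial: a 175.75 cm² bed, two valve zones of
    three segments, zone 1 loaded with dried soil (5 % moisture) and zone 2
    with saturated soil (95 %), a 500 mL / 194.60 s flow calibration shared
    by both valves, and a dry-high affine sensor map raw = 1023 − 9·moisture.
    """

    n_zones: int = 2
    sensors_per_zone: int = 3
    bed_area_cm2: float = 175.75
    drying_rate_pct_per_min: float = 0.5
    infiltration_gain_pct_per_ml: float = 0.3
    sensor_intercept: float = 1023.0
    sensor_slope: float = -9.0  # counts per % moisture; negative = dry-high
    sensor_noise_sd: float = 8.0
    process_noise_sd: float = 0.02
    flow: FlowCalibration = field(default_factory=FlowCalibration)
    tank_capacity_ml: float = 10000.0
    initial_moisture: tuple[float, ...] = (5.0, 5.0, 5.0, 95.0, 95.0, 95.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.drying_rate_pct_per_min, self.infiltration_gain_pct_per_ml,
               self.sensor_noise_sd, self.process_noise_sd) < 0:
            raise ValueError("rates and noise levels must be non-negative")
        if self.sensor_slope >= 0:
            raise ValueError("sensor calibration must be monotone decreasing (dry-high)")
        if self.bed_area_cm2 <= 0:
            raise ValueError("bed area must be positive")
        n = self.n_zones * self.sensors_per_zone
        if len(self.initial_moisture) != n:
            raise ValueError(f"initial_moisture needs {n} segment values")
        if any(not 0 <= m <= 100 for m in self.initial_moisture):
            raise ValueError("initial moisture must lie in [0, 100]")

    @property
    def n_segments(self) -> int:
        return self.n_zones * self.sensors_per_zone

    @property
    def group_map(self) -> tuple[int, ...]:
        return tuple(z for z in range(self.n_zones)
                     for _ in range(self.sensors_per_zone))

    @property
    def segment_areas_cm2(self) -> np.ndarray:
        return np.full(self.n_segments, self.bed_area_cm2 / self.n_segments)

    def raw_counts(self, moisture: np.ndarray, rng: np.random.Generator | None = None
                   ) -> np.ndarray:
        """Sensor model: affine dry-high map plus optional read noise."""
        raw = self.sensor_intercept + self.sensor_slope * np.asarray(moisture)
        if rng is not None and self.sensor_noise_sd > 0:
            raw = raw + rng.normal(0.0, self.sensor_noise_sd, raw.shape)
        return np.clip(raw, 0.0, 1023.0)


@dataclass
class BedState:
    """Mutable simulation state."""

    moisture: np.ndarray  # % per segment
    tank_ml: float
    time_s: float = 0.0


@dataclass
class SimResult:
    """Trajectories and accounting for one closed-loop run."""

    times: np.ndarray
    moisture: np.ndarray          # (steps, segments)
    readings: np.ndarray          # (steps, segments)
    commands: np.ndarray          # (steps, valves) integer steps
    dispensed_ml: np.ndarray      # (steps,) total over valves
    ledger: IrrigationLedger
    tank_start_ml: float
    tank_end_ml: float

    @property
    def total_dispensed_ml(self) -> float:
        return float(self.dispensed_ml.sum())

    @property
    def total_open_seconds(self) -> float:
        return self.ledger.total_open_seconds


def step(state: BedState, command: ValveCommand, dt: float, cfg: SoilBedConfig,
         rng: np.random.Generator | None = None) -> tuple[BedState, float]:
    """Advance the plant by ``dt`` seconds under a valve command.

    Returns the new state and the volume actually dispensed (mL), which is
    limited by the tank.  Dispensed water is allocated to the commanding
    valve's segments proportionally to area; moisture integrates infiltration
    minus drying plus seeded process noise, clipped to [0, 100].
    """
    fractions = np.asarray(command.fractions, dtype=float)
    want_ml = fractions * cfg.flow.rate_ml_per_s * dt
    total_want = float(want_ml.sum())
    if total_want > state.tank_ml:
        scale = state.tank_ml / total_want if total_want > 0 else 0.0
        want_ml = want_ml * scale
        total_want = float(want_ml.sum())
    groups = np.asarray(cfg.group_map)
    areas = cfg.segment_areas_cm2
    delta = np.zeros(cfg.n_segments)
    for z in range(cfg.n_zones):
        seg = groups == z
        share = areas[seg] / areas[seg].sum()
        delta[seg] = cfg.infiltration_gain_pct_per_ml * want_ml[z] * share
    moisture = state.moisture + delta - cfg.drying_rate_pct_per_min * dt / 60.0
    if rng is not None and cfg.process_noise_sd > 0:
        moisture = moisture + rng.normal(0.0, cfg.process_noise_sd, moisture.shape)
    moisture = np.clip(moisture, 0.0, 100.0)
    new = BedState(moisture=moisture, tank_ml=state.tank_ml - total_want,
                   time_s=state.time_s + dt)
    return new, total_want


def _make_decider(controller, cfg_ctrl):
    if callable(controller):
        return controller
    if controller == "average":
        acfg = cfg_ctrl if isinstance(cfg_ctrl, AvgControllerConfig) else AvgControllerConfig()
        return lambda f: average_decide(f, acfg)
    if controller == "fuzzy":
        fcfg = cfg_ctrl if isinstance(cfg_ctrl, FuzzyConfig) else FuzzyConfig()
        system = fcfg.system()
        return lambda f: fuzzy_decide(f, system=system)
    raise ValueError("controller must be callable, 'average' or 'fuzzy'")


def run_experiment(cfg: SoilBedConfig, controller="fuzzy",
                   duration_s: float = 3600.0, control_interval_s: float = 1.0,
                   controller_cfg=None, label: str | None = None) -> SimResult:
    """Sense → decide → actuate loop at a fixed control interval.

    ``controller`` is ``"fuzzy"``, ``"average"`` or a callable mapping a
    SensorFrame to a ValveCommand.  Seeded through ``cfg.seed``; identical
    configs give identical results.
    """
    rng = np.random.default_rng(cfg.seed)
    decide = _make_decider(controller, controller_cfg)
    n_steps = int(round(duration_s / control_interval_s))
    state = BedState(moisture=np.asarray(cfg.initial_moisture, dtype=float),
                     tank_ml=cfg.tank_capacity_ml)
    times = np.empty(n_steps)
    moist = np.empty((n_steps, cfg.n_segments))
    reads = np.empty((n_steps, cfg.n_segments))
    cmds = np.empty((n_steps, cfg.n_zones), dtype=int)
    disp = np.empty(n_steps)
    open_equiv_s = 0.0
    for i in range(n_steps):
        raw = cfg.raw_counts(state.moisture, rng)
        frame = SensorFrame(readings=raw, timestamp=state.time_s,
                            group_map=cfg.group_map)
        command = decide(frame)
        state, dispensed = step(state, command, control_interval_s, cfg, rng)
        open_equiv_s += sum(command.fractions) * control_interval_s
        times[i] = state.time_s
        moist[i] = state.moisture
        reads[i] = raw
        cmds[i] = command.steps
        disp[i] = dispensed
    ledger = IrrigationLedger(label=label or str(controller), calibration=cfg.flow)
    ledger.add_entry("run", open_equiv_s, float(disp.sum()))
    return SimResult(times=times, moisture=moist, readings=reads, commands=cmds,
                     dispensed_ml=disp, ledger=ledger,
                     tank_start_ml=cfg.tank_capacity_ml, tank_end_ml=state.tank_ml)


def compare_controllers(cfg: SoilBedConfig, duration_s: float = 3600.0,
                        seeds=range(20), control_interval_s: float = 1.0
                        ) -> dict:
    """Run both controllers on identical initial states and noise streams.

    For each seed the average-value and fuzzy controllers face the same bed
    and the same random stream; the report gives per-seed totals, the
    volume/open-time reductions and their across-seed dispersion.
    """
    rows = []
    for s in seeds:
        c = replace(cfg, seed=int(s))
        res_avg = run_experiment(c, "average", duration_s, control_interval_s)
        res_fuz = run_experiment(c, "fuzzy", duration_s, control_interval_s)
        rows.append({
            "seed": int(s),
            "average_ml": res_avg.total_dispensed_ml,
            "fuzzy_ml": res_fuz.total_dispensed_ml,
            "average_open_s": res_avg.total_open_seconds,
            "fuzzy_open_s": res_fuz.total_open_seconds,
        })
    df = pd.DataFrame(rows)
    savings = compare_runs(
        _totals_ledger(df, "average", cfg.flow), _totals_ledger(df, "fuzzy", cfg.flow))
    pct = 100.0 * (df["average_ml"] - df["fuzzy_ml"]) / df["average_ml"]
    return {
        "per_seed": df,
        "fuzzy_wins_volume": int((df["fuzzy_ml"] < df["average_ml"]).sum()),
        "fuzzy_wins_open_time": int((df["fuzzy_open_s"] < df["average_open_s"]).sum()),
        "n_seeds": len(df),
        "volume_saving_pct_mean": float(pct.mean()),
        "volume_saving_pct_sd": float(pct.std(ddof=1)) if len(df) > 1 else 0.0,
        "totals": savings,
    }


def _totals_ledger(df: pd.DataFrame, name: str, flow: FlowCalibration) -> IrrigationLedger:
    led = IrrigationLedger(label=name, calibration=flow)
    for _, r in df.iterrows():
        led.add_entry(f"seed {int(r['seed'])}", r[f"{name}_open_s"], r[f"{name}_ml"])
    return led


# ---------------------------------------------------------------------------
# Synthetic fixture generators


def generate_sensor_trace(cfg: SoilBedConfig | None = None,
                          pattern: str = "progressive-wetting",
                          n_rows: int = 20, seed: int = 0) -> pd.DataFrame:
    """Synthetic raw-count trace shaped like the printed trial scenarios.

    ``progressive-wetting`` starts every sensor dry (~990 counts) and wets
    one valve group at a time down to ~200; ``static`` holds a mid-range
    level.  Columns: timestamp, s1..sN.
    """
    if cfg is None:
        cfg = SoilBedConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n_segments
    rows = np.empty((n_rows, n))
    if pattern == "progressive-wetting":
        # group g starts dropping after a staggered onset, reaching wet level
        onsets = np.linspace(0.2, 0.6, cfg.n_zones) * n_rows
        for i in range(n_rows):
            for j in range(n):
                g = cfg.group_map[j]
                if i < onsets[g]:
                    level = 990.0
                else:
                    frac = min(1.0, (i - onsets[g]) / (0.3 * n_rows))
                    level = 990.0 - frac * 790.0
                rows[i, j] = level
    elif pattern == "static":
        rows[:] = 500.0
    else:
        raise ValueError("pattern must be 'progressive-wetting' or 'static'")
    rows = np.clip(rows + rng.normal(0, cfg.sensor_noise_sd, rows.shape), 0, 1023)
    df = pd.DataFrame(rows.round(0), columns=[f"s{j+1}" for j in range(n)])
    df.insert(0, "timestamp", np.arange(n_rows, dtype=float))
    return df


def generate_scene(shape: tuple[int, int] = (40, 40), patches: int = 3,
                   seed: int = 0, pixel_size: float = 30.0) -> BandStack:
    """Synthetic multiband reflectance scene with vegetation and saline patches.

    Background is bare soil (moderate red/green, low NIR contrast); each
    vegetation patch raises NIR and lowers red (high NDVI); saline patches
    raise green against SWIR (high NDSI).  Reflectances stay in [0, 1].
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    green = rng.normal(0.12, 0.01, shape)
    red = rng.normal(0.15, 0.01, shape)
    nir = rng.normal(0.22, 0.02, shape)
    swir = rng.normal(0.20, 0.02, shape)

    def _patch():
        r0 = rng.integers(0, rows - rows // 4)
        c0 = rng.integers(0, cols - cols // 4)
        h = rng.integers(rows // 8, rows // 4)
        w = rng.integers(cols // 8, cols // 4)
        return slice(r0, r0 + h), slice(c0, c0 + w)

    for _ in range(patches):
        sl = _patch()  # healthy vegetation: strong NIR, absorbed red
        nir[sl] = rng.normal(0.55, 0.03, nir[sl].shape)
        red[sl] = rng.normal(0.06, 0.01, red[sl].shape)
        green[sl] = rng.normal(0.10, 0.01, green[sl].shape)
    for _ in range(max(1, patches // 2)):
        sl = _patch()  # salt-affected soil: bright green band vs SWIR
        green[sl] = rng.normal(0.35, 0.02, green[sl].shape)
        swir[sl] = rng.normal(0.12, 0.01, swir[sl].shape)
    clip = lambda a: np.clip(a, 0.0, 1.0)  # noqa: E731
    return BandStack(green=clip(green), red=clip(red), nir=clip(nir),
                     swir=clip(swir), pixel_size=pixel_size)


def generate_weather(n_days: int = 100, seed: int = 0) -> pd.DataFrame:
    """Synthetic daily Penman–Monteith input records.

    Temperature and humidity draw es/ea/Δ through the standard auxiliary
    formulas, so every row satisfies the weather-record invariants.  Columns:
    rn, g, t, u2, es, ea, delta, gamma.
    """
    rng = np.random.default_rng(seed)
    t = rng.uniform(10.0, 38.0, n_days)
    rh = rng.uniform(35.0, 90.0, n_days)
    rn = rng.uniform(8.0, 22.0, n_days)
    g = rn * rng.uniform(0.05, 0.15, n_days)
    u2 = rng.uniform(0.0, 5.0, n_days)
    es = np.array([saturation_vapor_pressure(x) for x in t])
    ea = es * rh / 100.0
    delta = np.array([vapor_pressure_slope(x) for x in t])
    gamma = np.full(n_days, psychrometric_constant(0.0))
    return pd.DataFrame({"rn": rn, "g": g, "t": t, "u2": u2, "es": es,
                         "ea": ea, "delta": delta, "gamma": gamma})
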