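"""Global carbon reservoir, CO2-climate mapping, and the coupled driver.

A single lumped atmosphere-ocean carbon inventory evolves under

    dC/dt = degassing - silicate weathering - organic burial

with carbonate weathering treated as carbon-neutral on this timescale
(returned as deposition).  Relative CO2 is the inventory over a reference
inventory, and global average surface temperature (GAST) follows the
standard logarithmic map ``t_ref + S * log2(RCO2)``.

Every carbon-cycle timestep rebuilds the gridded climate at the current
GAST anomaly, re-seeds the vegetation kernel and spins it to steady state,
converts the resulting NPP field into weathering enhancement and the global
biomass into organic burial, and advances the inventory by an explicit
Euler step with an adaptive timestep (nominally 100 kyr, continuously
varied for stability).  Rate constants are calibrated once so a chosen
reference world balances reference degassing at RCO2 = 1 with fixed sink
shares.  Runs either converge to a steady state or end in a classified
failure (runaway hot/cold climate, vegetation extinction, or
non-convergence) -- failures are data, not exceptions.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import pandas as pd

from . import vegetation as vg
from . import weathering as wx
from .worlds import ClimateField, ClimateParams, ForcingState, WorldGrid, synth_climate

__all__ = [
    "CarbonParams",
    "CarbonState",
    "CouplerConfig",
    "ModelParams",
    "RunResult",
    "CalibrationError",
    "REFERENCE_FORCING",
    "gast_from_rco2",
    "carbon_tendency",
    "evaluate_fluxes",
    "calibrate_reference",
    "step_coupled",
    "run_to_steady",
    "run_history",
]

REFERENCE_FORCING = ForcingState(time_Ma=0.0, o2_mixing_ratio=0.21, degassing_rel=1.0)


class CalibrationError(RuntimeError):
    """Reference-world calibration could not balance the carbon cycle."""


@dataclass
class CarbonParams:
    """Reservoir-scale constants.

    ``f_degas_ref`` (mol C/yr) and ``c_ref`` (mol C) set the scale of the
    carbon cycle; neither is pinned by the mechanism, which cares only about
    relative CO2.  Sink shares define how reference degassing is split at
    calibration: silicate weathering 80%, land organic burial 10%, marine
    organic burial 10%.  ``baseline_biomass`` (gC) is the reference world's
    steady global biomass, fixed at calibration so v_rel = 1 there.
    """

    f_degas_ref: float = 8.0e12   # mol C/yr
    c_ref: float = 3.2e18         # mol C at RCO2 = 1
    sink_share_sil: float = 0.8
    sink_share_locb: float = 0.1
    sink_share_mocb: float = 0.1
    carb_ref_ratio: float = 0.5   # carbonate flux / degassing at reference (diagnostic)
    baseline_biomass: float = float("nan")

    def __post_init__(self) -> None:
        shares = self.sink_share_sil + self.sink_share_locb + self.sink_share_mocb
        if abs(shares - 1.0) > 1e-9:
            raise ValueError("sink shares must sum to 1")
        if self.f_degas_ref <= 0 or self.c_ref <= 0:
            raise ValueError("f_degas_ref and c_ref must be > 0")


@dataclass
class CarbonState:
    """Lumped atmosphere-ocean carbon inventory and derived climate."""

    atm_ocean_C: float  # mol C
    rco2: float
    gast: float         # degC

    @classmethod
    def from_rco2(cls, rco2: float, carbon: CarbonParams,
                  config: "CouplerConfig") -> "CarbonState":
        if rco2 <= 0:
            raise ValueError("rco2 must be > 0")
        return cls(atm_ocean_C=rco2 * carbon.c_ref, rco2=rco2,
                   gast=gast_from_rco2(rco2, config))


@dataclass
class CouplerConfig:
    """Timestepping and climate-map configuration."""

    dt_init: float = 1.0e5       # yr
    dt_min: float = 1.0e3
    dt_max: float = 1.0e6
    step_shrink: float = 0.5
    step_grow: float = 1.2
    stability_threshold: float = 0.02  # max |d rco2| / rco2 per step
    steady_tol: float = 1.0e-4   # |tendency| < steady_tol * f_degas_ref
    max_steps: int = 2000
    co2_bounds: tuple[float, float] = (0.01, 16.0)
    climate_sensitivity: float = 5.0  # degC per CO2 doubling
    t_ref: float = 14.0          # GAST at RCO2 = 1

    def __post_init__(self) -> None:
        if not self.dt_min <= self.dt_init <= self.dt_max:
            raise ValueError("need dt_min <= dt_init <= dt_max")
        if self.steady_tol <= 0:
            raise ValueError("steady_tol must be > 0")
        if not 0 < self.step_shrink < 1 or self.step_grow <= 1:
            raise ValueError("need 0 < step_shrink < 1 and step_grow > 1")
        lo, hi = self.co2_bounds
        if not 0 < lo < 1 < hi:
            raise ValueError("co2_bounds must straddle 1")


@dataclass
class ModelParams:
    """Bundle of all module parameter blocks used by the coupled driver."""

    photosynthesis: vg.PhotosynthesisParams = field(default_factory=vg.PhotosynthesisParams)
    pfts: dict = field(default_factory=lambda: dict(vg.DEFAULT_PFTS))
    climate: ClimateParams = field(default_factory=ClimateParams)
    weathering: wx.WeatheringParams = field(default_factory=wx.WeatheringParams)
    carbon: CarbonParams = field(default_factory=CarbonParams)


@dataclass
class RunResult:
    """Outcome of a coupled run; failures are classified, never raised."""

    success: bool
    failure_mode: str  # none | runaway_hot | runaway_cold | extinction | no_convergence
    trajectory: pd.DataFrame
    final_state: CarbonState
    final_vegetation: vg.VegetationState | None
    final_weathering: wx.WeatheringState | None

    @property
    def steady_rco2(self) -> float:
        return self.final_state.rco2


def gast_from_rco2(rco2: float, config: CouplerConfig) -> float:
    """GAST (degC) from relative CO2 via logarithmic climate sensitivity."""
    if rco2 <= 0:
        raise ValueError("rco2 must be > 0")
    return config.t_ref + config.climate_sensitivity * math.log2(rco2)


def carbon_tendency(weathering: wx.WeatheringState, forcing: ForcingState,
                    carbon: CarbonParams) -> float:
    """dC/dt (mol C/yr): degassing minus silicate drawdown and organic burial.

    Carbonate weathering is carbon-neutral here (weathered then redeposited),
    so it does not appear in the balance.
    """
    return (forcing.degassing_rel * carbon.f_degas_ref
            - weathering.total_sil
            - weathering.burial_land
            - weathering.burial_marine)


def evaluate_fluxes(rco2: float, forcing: ForcingState, world: WorldGrid,
                    params: ModelParams, config: CouplerConfig,
                    tol: float = 0.01
                    ) -> tuple[vg.VegetationState, wx.WeatheringState, float, float]:
    """One full vegetation-weathering evaluation at a given relative CO2.

    Builds the climate at the implied GAST anomaly, re-seeds and spins the
    vegetation kernel, evaluates per-cell weathering enhancement and global
    fluxes, and returns (vegetation, weathering, tendency, gast).
    """
    gast = gast_from_rco2(rco2, config)
    climate = synth_climate(world, forcing, gast - config.t_ref, params.climate)
    npp, dom = vg.npp_grid(climate, forcing, rco2, world,
                           params.pfts, params.photosynthesis)
    veg = vg.spin_to_steady_biomass(npp, forcing.o2_mixing_ratio,
                                    tol=tol, dominant_pft=dom)
    weath = wx.global_weathering(climate, veg, world, rco2, params.weathering)
    if math.isfinite(params.carbon.baseline_biomass):
        veg.v_rel = vg.relative_vegetation(veg, world, params.carbon.baseline_biomass)
        weath.burial_land, weath.burial_marine = wx.organic_burial(
            veg.v_rel, params.weathering)
    tendency = carbon_tendency(weath, forcing, params.carbon)
    return veg, weath, tendency, gast


def calibrate_reference(world: WorldGrid, params: ModelParams,
                        config: CouplerConfig,
                        forcing: ForcingState = REFERENCE_FORCING) -> ModelParams:
    """Scale rate constants so ``world`` balances reference degassing at RCO2=1.

    Silicate k constants are rescaled together (preserving their ratio) so
    total silicate weathering equals ``sink_share_sil * f_degas_ref``; land
    and marine burial constants are set to their shares (the reference world
    defines v_rel = 1); the carbonate constant is scaled to its diagnostic
    reference ratio.  Idempotent; returns a new ModelParams.
    """
    cb = params.carbon
    gast = gast_from_rco2(1.0, config)
    climate = synth_climate(world, forcing, gast - config.t_ref, params.climate)
    npp, dom = vg.npp_grid(climate, forcing, 1.0, world,
                           params.pfts, params.photosynthesis)
    veg = vg.spin_to_steady_biomass(npp, forcing.o2_mixing_ratio, dominant_pft=dom)
    weath = wx.global_weathering(climate, veg, world, 1.0, params.weathering)
    if weath.total_sil <= 0 or weath.total_carb <= 0:
        raise CalibrationError("reference world has zero weatherable flux")
    baseline = vg.total_biomass(veg, world)
    if baseline <= 0:
        raise CalibrationError("reference world supports no vegetation")
    f = cb.f_degas_ref
    sil_scale = cb.sink_share_sil * f / weath.total_sil
    carb_scale = cb.carb_ref_ratio * f / weath.total_carb
    new_wx = dataclasses.replace(
        params.weathering,
        k_sil_granite=params.weathering.k_sil_granite * sil_scale,
        k_sil_basalt=params.weathering.k_sil_basalt * sil_scale,
        k_carb=params.weathering.k_carb * carb_scale,
        k_locb=cb.sink_share_locb * f,
        k_mocb=cb.sink_share_mocb * f,
    )
    new_cb = dataclasses.replace(cb, baseline_biomass=baseline)
    return dataclasses.replace(params, weathering=new_wx, carbon=new_cb)


def _shrink_dt_for_stability(rco2: float, tendency: float, dt: float,
                             carbon: CarbonParams, config: CouplerConfig
                             ) -> tuple[float, bool]:
    """Shrink dt (x step_shrink) until the relative CO2 step is stable."""
    shrunk = False
    while dt > config.dt_min:
        d_rco2 = tendency * dt / carbon.c_ref
        if abs(d_rco2) / rco2 <= config.stability_threshold:
            break
        dt *= config.step_shrink
        shrunk = True
    return max(dt, config.dt_min), shrunk


def step_coupled(state: CarbonState, forcing: ForcingState, world: WorldGrid,
                 params: ModelParams, config: CouplerConfig,
                 dt: float | None = None
                 ) -> tuple[CarbonState, vg.VegetationState, wx.WeatheringState,
                            float, float]:
    """One coupled carbon-cycle step with adaptive timestep.

    Returns (new state, vegetation, weathering, dt_used, dt_next).  The
    explicit Euler update is retried at smaller dt whenever the relative CO2
    change would exceed the stability threshold; otherwise dt grows by
    ``step_grow`` up to ``dt_max``.
    """
    dt = config.dt_init if dt is None else dt
    veg, weath, tendency, gast = evaluate_fluxes(
        state.rco2, forcing, world, params, config)
    dt_used, shrunk = _shrink_dt_for_stability(
        state.rco2, tendency, dt, params.carbon, config)
    inv = state.atm_ocean_C + tendency * dt_used
    rco2 = inv / params.carbon.c_ref
    new_state = CarbonState(atm_ocean_C=inv, rco2=rco2,
                            gast=gast_from_rco2(rco2, config) if rco2 > 0 else float("nan"))
    dt_next = dt_used if shrunk else min(dt_used * config.step_grow, config.dt_max)
    return new_state, veg, weath, dt_used, dt_next


_TRAJ_COLS = ("time_yr", "rco2", "gast_C", "v_rel", "habitable_fraction",
              "habitable_area_m2", "F_sil", "F_carb", "F_locb", "dt")


def run_to_steady(world: WorldGrid, forcing: ForcingState, params: ModelParams,
                  config: CouplerConfig | None = None,
                  rco2_init: float = 1.0) -> RunResult:
    """Run the coupled system until the carbon cycle balances.

    Steady state is declared when |dC/dt| falls below
    ``steady_tol * f_degas_ref``.  Leaving ``co2_bounds`` classifies the run
    as a hot/cold runaway; total loss of habitable area away from balance is
    an extinction; exhausting ``max_steps`` is non-convergence.  A sign flip
    of the tendency between consecutive steps halves the timestep to damp
    limit cycles of the explicit integrator.
    """
    config = config or CouplerConfig()
    cb = params.carbon
    if not math.isfinite(cb.baseline_biomass):
        raise ValueError("params are uncalibrated; run calibrate_reference first")
    state = CarbonState.from_rco2(rco2_init, cb, config)
    dt = config.dt_init
    time = 0.0
    prev_tendency: float | None = None
    rows: list[tuple] = []
    veg = weath = None
    failure = "no_convergence"
    for _ in range(config.max_steps):
        veg, weath, tendency, gast = evaluate_fluxes(
            state.rco2, forcing, world, params, config)
        hab_frac, hab_area = vg.habitable_area(veg, world)
        # dt column is patched to the dt actually used to leave this state
        rows.append([time, state.rco2, gast, veg.v_rel, hab_frac, hab_area,
                     weath.total_sil, weath.total_carb, weath.burial_land, 0.0])
        if abs(tendency) < config.steady_tol * cb.f_degas_ref:
            failure = "none"
            break
        if hab_frac == 0.0:
            failure = "extinction"
            break
        if prev_tendency is not None and tendency * prev_tendency < 0:
            dt = max(dt * config.step_shrink, config.dt_min)
            grow = False
        else:
            grow = True
        prev_tendency = tendency
        dt_used, shrunk = _shrink_dt_for_stability(
            state.rco2, tendency, dt, cb, config)
        rows[-1][-1] = dt_used
        inv = state.atm_ocean_C + tendency * dt_used
        rco2 = inv / cb.c_ref
        time += dt_used
        lo, hi = config.co2_bounds
        if rco2 >= hi:
            failure = "runaway_hot"
            state = CarbonState(inv, rco2, float("nan"))
            break
        if rco2 <= lo:
            failure = "runaway_cold"
            state = CarbonState(inv, rco2, float("nan"))
            break
        state = CarbonState.from_rco2(rco2, cb, config)
        if shrunk:
            dt = dt_used
        elif grow:
            dt = min(dt_used * config.step_grow, config.dt_max)
    trajectory = pd.DataFrame(rows, columns=_TRAJ_COLS)
    return RunResult(success=(failure == "none"), failure_mode=failure,
                     trajectory=trajectory, final_state=state,
                     final_vegetation=veg, final_weathering=weath)


def run_history(world: WorldGrid, segments: list[tuple[float, ForcingState]],
                params: ModelParams, config: CouplerConfig | None = None,
                rco2_init: float = 1.0) -> RunResult:
    """Step through a piecewise-constant forcing history.

    ``segments`` is a list of (duration_yr, forcing) pairs; within each
    segment the coupler advances with its adaptive timestep (capped at the
    segment boundary).  Returns a single RunResult whose trajectory spans
    the whole history; steady state is not required.
    """
    config = config or CouplerConfig()
    cb = params.carbon
    if not math.isfinite(cb.baseline_biomass):
        raise ValueError("params are uncalibrated; run calibrate_reference first")
    state = CarbonState.from_rco2(rco2_init, cb, config)
    dt = config.dt_init
    time = 0.0
    rows: list[tuple] = []
    veg = weath = None
    failure = "none"
    for duration, forcing in segments:
        seg_end = time + duration
        while time < seg_end and failure == "none":
            veg, weath, tendency, gast = evaluate_fluxes(
                state.rco2, forcing, world, params, config)
            hab_frac, hab_area = vg.habitable_area(veg, world)
            rows.append([time, state.rco2, gast, veg.v_rel, hab_frac, hab_area,
                         weath.total_sil, weath.total_carb, weath.burial_land, 0.0])
            dt_used, shrunk = _shrink_dt_for_stability(
                state.rco2, tendency, min(dt, seg_end - time), cb, config)
            dt_used = min(dt_used, seg_end - time)
            rows[-1][-1] = dt_used
            inv = state.atm_ocean_C + tendency * dt_used
            rco2 = inv / cb.c_ref
            time += dt_used
            lo, hi = config.co2_bounds
            if rco2 >= hi:
                failure = "runaway_hot"
            elif rco2 <= lo:
                failure = "runaway_cold"
            else:
                state = CarbonState.from_rco2(rco2, cb, config)
                dt = dt_used if shrunk else min(dt_used * config.step_grow, config.dt_max)
        if failure != "none":
            break
    trajectory = pd.DataFrame(rows, columns=_TRAJ_COLS)
    return RunResult(success=(failure == "none"), failure_mode=failure,
                     trajectory=trajectory, final_state=state,
                     final_vegetation=veg, final_weathering=weath)
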