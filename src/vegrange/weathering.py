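"""Biotic weathering enhancement, weathering fluxes and organic burial.

The core coupling quantity is the per-cell biotic enhancement factor

    f_biota = 0.0005 * NPP + f_minbiota * RCO2**r

an affine function of local NPP (gC m-2 yr-1) plus the GEOCARB-style
pH-driven abiotic term ``f_minbiota * RCO2**r`` (f_minbiota = 0.32,
r = 0.25) that bare cells recover at NPP = 0.  At the vegetation kernel's
NPP ceiling of 3200 gC m-2 yr-1 and RCO2 = 1 the enhancement is exactly
6x the bare-ground value.

Per-cell silicate weathering uses runoff-linear kinetics with an Arrhenius
temperature dependence split between basaltic and granitic lithology;
carbonate weathering shares the runoff * f_biota kernel with a single rate
constant.  Rate constants are calibration targets (see the carbon-cycle
module), not first-principles values; erosion dependence is folded into
them.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vegetation import VegetationState
from .worlds import ClimateField, WorldGrid

GAS_CONSTANT = 8.314      # J mol-1 K-1
T_REF_KELVIN = 288.15     # 15 degC kinetic reference

__all__ = [
    "WeatheringParams",
    "WeatheringState",
    "biotic_enhancement",
    "cell_silicate_flux",
    "cell_carbonate_flux",
    "global_weathering",
    "organic_burial",
]


@dataclass
class WeatheringParams:
    """Enhancement law constants and (calibratable) rate constants.

    Activation energies are in kJ/mol; the k constants carry the units that
    make ``area * runoff * f_biota * k`` come out in mol C/yr and are scaled
    at calibration so the reference world balances reference degassing.
    """

    npp_slope: float = 0.0005   # (gC m-2 yr-1)^-1
    f_minbiota: float = 0.32
    r: float = 0.25             # abiotic CO2 exponent, conservative end of 0.25-0.5
    k_sil_granite: float = 1.0
    k_sil_basalt: float = 1.0
    act_energy_granite: float = 63.0  # kJ/mol
    act_energy_basalt: float = 50.0   # kJ/mol
    k_carb: float = 1.0
    k_locb: float = 4.5e11      # mol C/yr land organic burial at v_rel = 1
    k_mocb: float = 4.5e11      # mol C/yr marine organic burial (held constant)

    def __post_init__(self) -> None:
        if self.npp_slope <= 0:
            raise ValueError("npp_slope must be > 0")
        if not 0 < self.f_minbiota < 1:
            raise ValueError("f_minbiota must lie in (0, 1)")
        if not 0.25 <= self.r <= 0.5:
            raise ValueError("r must lie in [0.25, 0.5]")
        for name in ("k_sil_granite", "k_sil_basalt", "k_carb", "k_locb", "k_mocb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class WeatheringState:
    """Per-cell enhancement and fluxes plus global totals (mol C/yr)."""

    f_biota: np.ndarray
    sil_flux: np.ndarray
    carb_flux: np.ndarray
    total_sil: float
    total_carb: float
    burial_land: float
    burial_marine: float


def biotic_enhancement(npp, rco2: float, params: WeatheringParams | None = None):
    """f_biota = npp_slope * NPP + f_minbiota * RCO2**r (scalar or array)."""
    if rco2 <= 0:
        raise ValueError("rco2 must be > 0")
    p = params or WeatheringParams()
    out = p.npp_slope * np.asarray(npp, float) + p.f_minbiota * rco2 ** p.r
    return float(out) if out.ndim == 0 else out


def _arrhenius(temperature_c, act_energy_kj: float):
    t_k = np.asarray(temperature_c, float) + 273.15
    return np.exp((act_energy_kj * 1e3 / GAS_CONSTANT)
                  * (1.0 / T_REF_KELVIN - 1.0 / t_k))


def cell_silicate_flux(temperature_c, runoff, f_biota, basalt_fraction,
                       cell_area, params: WeatheringParams | None = None):
    """Silicate weathering flux, mol C/yr, for one cell or an array of cells.

    ``area * runoff * f_biota * sum_lith(frac * k_lith * Arrhenius(T))``;
    identically zero at zero runoff.
    """
    p = params or WeatheringParams()
    runoff = np.asarray(runoff, float)
    bf = np.asarray(basalt_fraction, float)
    kin = (bf * p.k_sil_basalt * _arrhenius(temperature_c, p.act_energy_basalt)
           + (1.0 - bf) * p.k_sil_granite * _arrhenius(temperature_c, p.act_energy_granite))
    flux = np.asarray(cell_area, float) * runoff * np.asarray(f_biota, float) * kin
    flux = np.where(runoff <= 0, 0.0, flux)
    return float(flux) if flux.ndim == 0 else flux


def cell_carbonate_flux(runoff, f_biota, cell_area,
                        params: WeatheringParams | None = None):
    """Carbonate weathering flux, mol C/yr: area * runoff * f_biota * k_carb."""
    p = params or WeatheringParams()
    runoff = np.asarray(runoff, float)
    flux = np.asarray(cell_area, float) * runoff * np.asarray(f_biota, float) * p.k_carb
    flux = np.where(runoff <= 0, 0.0, flux)
    return float(flux) if flux.ndim == 0 else flux


def organic_burial(v_rel: float, params: WeatheringParams | None = None
                   ) -> tuple[float, float]:
    """(land, marine) organic carbon burial, mol C/yr.

    Land burial scales with global relative vegetation; marine burial is held
    at its reference value in this reduced model.
    """
    if v_rel < 0:
        raise ValueError("v_rel must be >= 0")
    p = params or WeatheringParams()
    return p.k_locb * v_rel, p.k_mocb


def global_weathering(climate: ClimateField, veg: VegetationState,
                      grid: WorldGrid, rco2: float,
                      params: WeatheringParams | None = None) -> WeatheringState:
    """Per-cell enhancement and fluxes over a world, with global totals.

    f_biota is evaluated everywhere (ocean cells sit at the abiotic value but
    contribute no flux because their runoff is zero); cell fluxes already
    include cell area, so the totals are plain sums.  Burial terms are filled
    in by the coupler once a vegetation baseline is known; here they are 0.
    """
    p = params or WeatheringParams()
    if climate.temperature.shape != grid.shape or veg.npp.shape != grid.shape:
        raise ValueError("climate, vegetation and grid shapes do not match")
    f_biota = biotic_enhancement(veg.npp, rco2, p)
    sil = cell_silicate_flux(climate.temperature, climate.runoff, f_biota,
                             grid.basalt_fraction, grid.cell_area, p)
    carb = cell_carbonate_flux(climate.runoff, f_biota, grid.cell_area, p)
    return WeatheringState(
        f_biota=f_biota,
        sil_flux=sil,
        carb_flux=carb,
        total_sil=float(sil.sum()),
        total_carb=float(carb.sum()),
        burial_land=0.0,
        burial_marine=0.0,
    )
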