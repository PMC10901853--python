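"""Gridded vegetation kernel: NPP, turnover, steady-state biomass.

A deliberately fast, generalised photosynthetic biosphere in the tradition of
streamlined LPJ-derived dynamic vegetation models.  Per-cell net primary
productivity (NPP, gC m-2 yr-1) is a multiplicative-limitation product of
temperature, water, light, CO2 and O2 response factors for three broad plant
functional types (tropical, temperate, boreal).  Standing biomass obeys the
annual recurrence ``B <- B + NPP - turnover*B`` from a uniform colonisation
seed, whose fixed point is NPP/turnover; turnover rises with atmospheric O2
to represent fire.  Cells with no runoff, or annual mean temperature below
-10 degC, or temperature outside every functional type's window, carry no
vegetation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .worlds import ClimateField, ForcingState, WorldGrid

__all__ = [
    "PhotosynthesisParams",
    "PFTParams",
    "DEFAULT_PFTS",
    "VegetationState",
    "ConvergenceError",
    "insolation_factor",
    "leaf_respiration_rate",
    "turnover_fraction",
    "npp_cell",
    "npp_grid",
    "spin_to_steady_biomass",
    "habitable_area",
    "relative_vegetation",
    "total_biomass",
    "SEED_BIOMASS",
]

SEED_BIOMASS = 2.5e4  # gC m-2, average present-day biomass used to re-seed
T_HABITABLE_MIN = -10.0  # degC, below which no cell carries biomass
SOLAR_AGE_MYR = 4570.0
LUMINOSITY_SLOPE = 0.4


class ConvergenceError(RuntimeError):
    """Biomass spin-up failed to reach steady state within max_iter."""


def insolation_factor(lat_deg, time_Ma: float):
    """Relative insolation: cos(latitude) times past solar luminosity.

    Normalised to 1 at the equator at the present day.  Luminosity follows
    the standard faint-young-sun scaling ``1 / (1 + 0.4 t / 4570)`` with t in
    Myr before present (about a 5% reduction in the early Phanerozoic).
    """
    lum = 1.0 / (1.0 + LUMINOSITY_SLOPE * time_Ma / SOLAR_AGE_MYR)
    return np.cos(np.radians(lat_deg)) * lum


def leaf_respiration_rate(h: float, a: float) -> float:
    """Leaf respiration fraction s = (24/h) * a for h daylight hours."""
    if not 0 < h <= 24:
        raise ValueError("daylight hours h must lie in (0, 24]")
    if a < 0:
        raise ValueError("respiration coefficient a must be >= 0")
    return (24.0 / h) * a


def turnover_fraction(o2_mixing_ratio):
    """Annual biomass turnover, rising with O2 from fire: clamped to [0.08, 0.2].

    ``min(max(0.0092*(100*O2mr - 10), 0.08), 0.2)`` -- doubles between the
    present-day value (~0.1 at 21% O2) and its maximum of 0.2.
    """
    o2 = np.asarray(o2_mixing_ratio, float)
    out = np.clip(0.0092 * (100.0 * o2 - 10.0), 0.08, 0.2)
    return float(out) if np.isscalar(o2_mixing_ratio) else out


@dataclass
class PhotosynthesisParams:
    """Shared photosynthesis constants.

    ``npp_max`` is chosen so that the biotic weathering enhancement at the
    NPP ceiling is exactly 6x its bare-ground value at present-day CO2
    (0.0005*3200 + 0.32 = 6*0.32).  ``h=12`` reflects the no-seasonality
    assumption of equal day length everywhere; ``a`` is an LPJ-heritage
    leaf-respiration coefficient and a free parameter of this kernel.
    """

    npp_max: float = 3200.0      # gC m-2 yr-1
    a: float = 0.015             # leaf respiration coefficient
    h: float = 12.0              # daylight hours
    k_co2: float = 0.5           # CO2 half-saturation (relative CO2 units)
    o2_sensitivity: float = 0.3  # photorespiration slope
    runoff_half: float = 30.0    # mm yr-1 water half-saturation

    def __post_init__(self) -> None:
        if self.npp_max <= 0:
            raise ValueError("npp_max must be > 0")
        if not 0 < self.h <= 24:
            raise ValueError("h must lie in (0, 24]")
        if self.k_co2 <= 0 or self.runoff_half <= 0:
            raise ValueError("half-saturation constants must be > 0")

    @property
    def s(self) -> float:
        """Leaf respiration rate (24/h)*a."""
        return leaf_respiration_rate(self.h, self.a)


@dataclass(frozen=True)
class PFTParams:
    """Temperature-response ramp of one plant functional type (degC)."""

    name: str
    t_min: float
    t_opt_lo: float
    t_opt_hi: float
    t_max: float

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_opt_lo <= self.t_opt_hi < self.t_max):
            raise ValueError(f"invalid temperature ramp for PFT '{self.name}'")


DEFAULT_PFTS: dict[str, PFTParams] = {
    "tropical": PFTParams("tropical", 2.0, 25.0, 30.0, 55.0),
    "temperate": PFTParams("temperate", -4.0, 15.0, 25.0, 38.0),
    "boreal": PFTParams("boreal", -4.0, 10.0, 25.0, 38.0),
}
# dominant-type tie priority and integer codes (0 = none)
PFT_ORDER = ("tropical", "temperate", "boreal")
PFT_CODES = {name: i + 1 for i, name in enumerate(PFT_ORDER)}


def _g_temperature(temperature, pft: PFTParams):
    xp = [pft.t_min, pft.t_opt_lo, pft.t_opt_hi, pft.t_max]
    g = np.interp(temperature, xp, [0.0, 1.0, 1.0, 0.0])
    # np.interp clamps to the endpoint values, i.e. 0 outside [t_min, t_max]
    return np.where((np.asarray(temperature) <= pft.t_min)
                    | (np.asarray(temperature) >= pft.t_max), 0.0, g)


def npp_cell(temperature, runoff, insolation_rel, rco2: float,
             o2_mixing_ratio: float, pft: PFTParams,
             params: PhotosynthesisParams | None = None):
    """NPP of one functional type: capped multiplicative limitation.

    ``NPP = min(npp_max, npp_max * g_T * g_W * g_L * g_C * g_O * (1 - s))``
    with a saturating water response, a CO2 response normalised to 1 at
    relative CO2 = 1, and a photorespiration penalty above present-day O2.
    Zero wherever runoff is zero or temperature is below -10 degC or outside
    the functional type's window.  Accepts scalars or arrays.
    """
    if rco2 <= 0:
        raise ValueError("rco2 must be > 0")
    p = params or PhotosynthesisParams()
    g_t = _g_temperature(temperature, pft)
    runoff = np.asarray(runoff, float)
    g_w = runoff / (runoff + p.runoff_half)
    g_l = np.asarray(insolation_rel, float)
    g_c = rco2 * (1.0 + p.k_co2) / (rco2 + p.k_co2)
    g_o = np.clip(1.0 - p.o2_sensitivity * (o2_mixing_ratio - 0.21) / 0.21, 0.0, 1.1)
    npp = np.minimum(p.npp_max, p.npp_max * g_t * g_w * g_l * g_c * g_o * (1.0 - p.s))
    npp = np.where((runoff <= 0) | (np.asarray(temperature) < T_HABITABLE_MIN), 0.0, npp)
    return float(npp) if npp.ndim == 0 else npp


def npp_grid(climate: ClimateField, forcing: ForcingState, rco2: float,
             grid: WorldGrid, pfts: dict[str, PFTParams] | None = None,
             params: PhotosynthesisParams | None = None
             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell NPP and dominant functional type over a world.

    Each land cell takes the maximum NPP over the three functional types;
    ties resolve by the fixed priority tropical > temperate > boreal.  Ocean
    cells get NPP 0 and code 0.
    """
    pfts = pfts or DEFAULT_PFTS
    if climate.temperature.shape != grid.shape:
        raise ValueError("climate and grid shapes do not match")
    npp = np.zeros(grid.shape)
    dominant = np.zeros(grid.shape, np.int8)
    for name in PFT_ORDER:
        cand = npp_cell(climate.temperature, climate.runoff,
                        climate.insolation_rel, rco2,
                        forcing.o2_mixing_ratio, pfts[name], params)
        better = cand > npp  # strict: earlier (higher-priority) type keeps ties
        npp = np.where(better, cand, npp)
        dominant = np.where(better & (cand > 0), PFT_CODES[name], dominant)
    npp = np.where(grid.land_mask, npp, 0.0)
    dominant = np.where(grid.land_mask, dominant, 0).astype(np.int8)
    return npp, dominant


@dataclass
class VegetationState:
    """Steady-state vegetation over a world grid."""

    npp: np.ndarray              # gC m-2 yr-1
    biomass: np.ndarray          # gC m-2
    turnover: float              # yr-1 (global, O2-controlled)
    dominant_pft: np.ndarray     # int8 codes, 0 = none
    habitable: np.ndarray        # bool, biomass > 0
    iterations_to_converge: int
    v_rel: float = float("nan")  # set once a baseline total is known


def spin_to_steady_biomass(npp: np.ndarray, o2_mixing_ratio: float,
                           seed_biomass: float = SEED_BIOMASS,
                           tol: float = 0.01, max_iter: int = 2000,
                           dominant_pft: np.ndarray | None = None
                           ) -> VegetationState:
    """Iterate annual biomass updates from a uniform seed to steady state.

    Every habitable cell (NPP > 0) starts at ``seed_biomass`` — vegetation is
    re-established from scratch each time — and follows
    ``B <- B + NPP - turnover*B``.  Convergence is declared when the
    turnover-normalised annual change ``|dB| / (turnover * B)`` drops below
    ``tol`` in every habitable cell; because ``dB = turnover*(B* - B)`` this
    is exactly the relative distance to the fixed point ``B* = NPP/turnover``,
    so the returned biomass is guaranteed within ``tol`` of the closed form.
    Cells with NPP = 0 are hard-zeroed and flagged uninhabitable up front.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if seed_biomass <= 0:
        raise ValueError("seed_biomass must be > 0")
    npp = np.asarray(npp, float)
    tau = turnover_fraction(o2_mixing_ratio)
    habitable = npp > 0
    b = np.where(habitable, float(seed_biomass), 0.0)
    if not habitable.any():
        return VegetationState(npp=npp, biomass=b, turnover=tau,
                               dominant_pft=_dom(dominant_pft, npp),
                               habitable=habitable, iterations_to_converge=0)
    for n in range(1, max_iter + 1):
        b_next = b + npp - tau * b
        delta = np.abs(b_next - b)
        if np.all(delta[habitable] <= tol * tau * b_next[habitable]):
            return VegetationState(npp=npp, biomass=b_next, turnover=tau,
                                   dominant_pft=_dom(dominant_pft, npp),
                                   habitable=habitable,
                                   iterations_to_converge=n)
        b = b_next
    worst = float(np.max(delta[habitable] / (tau * b[habitable])))
    raise ConvergenceError(
        f"biomass not steady after {max_iter} iterations "
        f"(worst normalised change {worst:.3g}, tol {tol:g})")


def _dom(dominant_pft: np.ndarray | None, npp: np.ndarray) -> np.ndarray:
    if dominant_pft is None:
        return np.zeros(npp.shape, np.int8)
    return np.asarray(dominant_pft, np.int8)


def habitable_area(state: VegetationState, grid: WorldGrid) -> tuple[float, float]:
    """(fraction of land area, absolute m^2) carrying nonzero biomass."""
    land_area = grid.land_area
    if land_area <= 0:
        raise ValueError("grid has zero land area")
    area = float(grid.cell_area[state.biomass > 0].sum())
    return area / land_area, area


def total_biomass(state: VegetationState, grid: WorldGrid) -> float:
    """Area-weighted global biomass, gC."""
    return float((state.biomass * grid.cell_area).sum())


def relative_vegetation(state: VegetationState, grid: WorldGrid,
                        baseline_total: float) -> float:
    """Global biomass relative to a baseline total (gC)."""
    if baseline_total <= 0:
        raise ValueError("baseline_total must be > 0")
    return total_biomass(state, grid) / baseline_total
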