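"""Synthetic worlds: lat-lon grids, land-mask generators and emulated climate.

This module stands in for the external GCM climate emulator that a full
spatially-resolved biogeochemical model would consume.  It builds equal-angle
spherical grids, generates supercontinent-like and dispersed continental
configurations, and synthesises physically plausible annual-mean temperature
and runoff fields: a warm wet equatorial band, dry subtropical belts, wetter
mid-latitudes, and arid continental interiors caused by the lack of moisture
transport far from any coastline.  User-supplied climate grids can be loaded
from netCDF or long-format CSV.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

R_EARTH = 6.371e6  # m

__all__ = [
    "R_EARTH",
    "WorldGrid",
    "ClimateField",
    "ForcingState",
    "ClimateParams",
    "make_grid",
    "make_supercontinent",
    "make_dispersed",
    "distance_to_coast",
    "count_components",
    "synth_climate",
    "save_world",
    "load_climate",
]


class WorldGenerationError(RuntimeError):
    """A land-mask generator could not satisfy its placement contract."""


# ---------------------------------------------------------------------------
# grid geometry
# ---------------------------------------------------------------------------

@dataclass
class WorldGrid:
    """Equal-angle lat-lon grid with a land mask and lithology fractions.

    Longitude is periodic; latitude is closed at the poles.  ``cell_area``
    follows the spherical band formula and depends only on latitude, so the
    total is exactly the area of the sphere.  ``basalt_fraction`` is the
    basaltic share of weatherable lithology per land cell (granite takes the
    remainder); it is zero on ocean cells.
    """

    n_lat: int
    n_lon: int
    lat_centers: np.ndarray  # (n_lat,) degrees, -90..90
    lon_centers: np.ndarray  # (n_lon,) degrees, 0..360
    cell_area: np.ndarray    # (n_lat, n_lon) m^2
    land_mask: np.ndarray    # (n_lat, n_lon) bool
    basalt_fraction: np.ndarray  # (n_lat, n_lon) in [0, 1], 0 on ocean

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def total_area(self) -> float:
        return float(self.cell_area.sum())

    @property
    def land_area(self) -> float:
        return float(self.cell_area[self.land_mask].sum())

    @property
    def lat2d(self) -> np.ndarray:
        return np.broadcast_to(self.lat_centers[:, None], self.shape)

    def coast_distance(self) -> np.ndarray:
        """BFS grid distance to the nearest ocean cell (cached per mask)."""
        key = self.land_mask.tobytes()
        cached = getattr(self, "_coast_cache", None)
        if cached is None or cached[0] != key:
            cached = (key, distance_to_coast(self))
            object.__setattr__(self, "_coast_cache", cached)
        return cached[1]

    def with_mask(self, land_mask: np.ndarray,
                  basalt_fraction: np.ndarray | float = 0.25) -> "WorldGrid":
        """New grid sharing geometry, with the given mask and lithology."""
        land_mask = np.asarray(land_mask, bool)
        if land_mask.shape != self.shape:
            raise ValueError("land_mask shape does not match grid")
        if np.isscalar(basalt_fraction):
            bf = np.where(land_mask, float(basalt_fraction), 0.0)
        else:
            bf = np.where(land_mask, np.asarray(basalt_fraction, float), 0.0)
        if bf.min() < 0 or bf.max() > 1:
            raise ValueError("basalt_fraction must lie in [0, 1]")
        return dataclasses.replace(self, land_mask=land_mask, basalt_fraction=bf)


def make_grid(n_lat: int, n_lon: int) -> WorldGrid:
    """Equal-angle grid; all-ocean until a mask generator is applied."""
    if n_lat < 2 or n_lon < 2:
        raise ValueError(f"grid needs n_lat >= 2 and n_lon >= 2, got ({n_lat}, {n_lon})")
    lat_edges = np.linspace(-90.0, 90.0, n_lat + 1)
    lat_centers = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    lon_centers = (np.arange(n_lon) + 0.5) * 360.0 / n_lon
    band = 2.0 * np.pi * R_EARTH**2 * np.diff(np.sin(np.radians(lat_edges))) / n_lon
    cell_area = np.repeat(band[:, None], n_lon, axis=1)
    shape = (n_lat, n_lon)
    return WorldGrid(
        n_lat=n_lat,
        n_lon=n_lon,
        lat_centers=lat_centers,
        lon_centers=lon_centers,
        cell_area=cell_area,
        land_mask=np.zeros(shape, bool),
        basalt_fraction=np.zeros(shape, float),
    )


# ---------------------------------------------------------------------------
# neighbourhood helpers (4-neighbour, longitude-periodic, latitude closed)
# ---------------------------------------------------------------------------

def _neighbor_any(mask: np.ndarray) -> np.ndarray:
    """Cells with at least one 4-neighbour inside ``mask``."""
    out = np.zeros_like(mask)
    out[:-1] |= mask[1:]
    out[1:] |= mask[:-1]
    out |= np.roll(mask, 1, axis=1)
    out |= np.roll(mask, -1, axis=1)
    return out


def _dilate8(mask: np.ndarray) -> np.ndarray:
    """``mask`` grown by its 8-neighbourhood (includes the mask itself)."""
    rolled = mask | np.roll(mask, 1, axis=1) | np.roll(mask, -1, axis=1)
    out = rolled.copy()
    out[:-1] |= rolled[1:]
    out[1:] |= rolled[:-1]
    return out


def _land_neighbor_count(mask: np.ndarray) -> np.ndarray:
    m = mask.astype(np.int8)
    cnt = np.zeros(mask.shape, np.int8)
    cnt[:-1] += m[1:]
    cnt[1:] += m[:-1]
    cnt += np.roll(m, 1, axis=1)
    cnt += np.roll(m, -1, axis=1)
    return cnt


def distance_to_coast(grid: WorldGrid) -> np.ndarray:
    """Per-cell BFS distance to the ocean: 0 on ocean, 1 on coastal land.

    An all-land mask has no coastline; its land cells are assigned
    ``n_lat + n_lon`` (farther than any reachable distance).
    """
    land = grid.land_mask
    dist = np.zeros(grid.shape, int)
    if land.all():
        dist[:] = grid.n_lat + grid.n_lon
        return dist
    reached = ~land
    d = 0
    while True:
        frontier = land & ~reached & _neighbor_any(reached)
        if not frontier.any():
            break
        d += 1
        dist[frontier] = d
        reached |= frontier
    return dist


def count_components(mask: np.ndarray) -> int:
    """Number of 4-connected components (longitude-periodic)."""
    remaining = np.asarray(mask, bool).copy()
    n = 0
    while remaining.any():
        n += 1
        i, j = np.argwhere(remaining)[0]
        comp = np.zeros_like(remaining)
        comp[i, j] = True
        while True:
            grown = remaining & (comp | _neighbor_any(comp))
            if grown.sum() == comp.sum():
                break
            comp = grown
        remaining &= ~comp
    return n


# ---------------------------------------------------------------------------
# land-mask generators
# ---------------------------------------------------------------------------

_COMPACTNESS_BASE = 3.0   # frontier weight = base ** (number of land neighbours)
_POLAR_LAT_LIMIT = 72.0   # discourage (not forbid) growth poleward of this
_POLAR_PENALTY = 0.02


def _grow_block(grid: WorldGrid, land: np.ndarray, allowed: np.ndarray,
                rng: np.random.Generator) -> float:
    """Grow ``land`` in place by one cell drawn from its weighted frontier.

    Returns the area of the added cell, or raises if the frontier is empty.
    """
    frontier = _neighbor_any(land) & ~land & allowed
    idx = np.argwhere(frontier)
    if len(idx) == 0:
        raise WorldGenerationError("block frontier exhausted before reaching target area")
    nnb = _land_neighbor_count(land)[idx[:, 0], idx[:, 1]].astype(float)
    w = _COMPACTNESS_BASE ** nnb
    polar = np.abs(grid.lat_centers[idx[:, 0]]) > _POLAR_LAT_LIMIT
    w = np.where(polar, w * _POLAR_PENALTY, w)
    k = rng.choice(len(idx), p=w / w.sum())
    i, j = idx[k]
    land[i, j] = True
    return float(grid.cell_area[i, j])


def make_supercontinent(grid: WorldGrid, land_fraction: float,
                        center_lat: float = 0.0, seed: int = 0,
                        basalt_fraction: float = 0.25) -> WorldGrid:
    """Single connected land block covering ~``land_fraction`` of the sphere.

    The block is grown from the cell nearest ``center_lat`` by a seeded,
    compactness-weighted accretion process, so it develops a deep interior
    (the geometry that produces large arid belts).  Total land area lands
    within one cell area of the target; same seed gives the same mask.
    """
    if not 0.0 < land_fraction < 1.0:
        raise ValueError("land_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    target = land_fraction * grid.total_area
    land = np.zeros(grid.shape, bool)
    i0 = int(np.argmin(np.abs(grid.lat_centers - center_lat)))
    j0 = grid.n_lon // 2
    land[i0, j0] = True
    area = float(grid.cell_area[i0, j0])
    allowed = np.ones(grid.shape, bool)
    while area < target:
        area += _grow_block(grid, land, allowed, rng)
    return grid.with_mask(land, basalt_fraction)


def make_dispersed(grid: WorldGrid, land_fraction: float, n_blocks: int,
                   seed: int = 0, basalt_fraction: float = 0.25,
                   center_lat: float = 0.0, lat_jitter: float = 20.0,
                   max_attempts: int = 25) -> WorldGrid:
    """``n_blocks`` disjoint land blocks of equal target area.

    Block seeds are spread evenly in longitude at latitudes drawn near
    ``center_lat`` (uniform jitter of +-``lat_jitter`` degrees), so that a
    fragmentation series (n_blocks = 1, 2, ...) varies geographic range
    without drifting the latitudinal land distribution -- the control that
    isolates the range -> weathering mechanism.  Blocks grow round-robin and
    are kept at least one ocean cell apart (no 8-neighbour contact).
    ``n_blocks=1`` degenerates to the supercontinent contract.  Total land
    area matches a supercontinent of equal ``land_fraction`` to within one
    cell.  Raises :class:`WorldGenerationError` if the blocks cannot be
    placed after ``max_attempts`` seedings.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if not 0.0 < land_fraction < 1.0:
        raise ValueError("land_fraction must lie strictly between 0 and 1")
    if n_blocks == 1:
        return make_supercontinent(grid, land_fraction, center_lat, seed,
                                   basalt_fraction)
    rng = np.random.default_rng(seed)
    target_total = land_fraction * grid.total_area
    per_block = target_total / n_blocks

    for _ in range(max_attempts):
        j0 = int(rng.integers(grid.n_lon))
        seeds: list[tuple[int, int]] = []
        for k in range(n_blocks):
            j = (j0 + (k * grid.n_lon) // n_blocks) % grid.n_lon
            lat = np.clip(center_lat + rng.uniform(-lat_jitter, lat_jitter),
                          -55.0, 55.0)
            i = int(np.argmin(np.abs(grid.lat_centers - lat)))
            seeds.append((i, j))
        blocks = []
        areas = []
        for (i, j) in seeds:
            b = np.zeros(grid.shape, bool)
            b[i, j] = True
            blocks.append(b)
            areas.append(float(grid.cell_area[i, j]))
        try:
            while sum(areas) < target_total:
                # most deficient block grows next
                k = int(np.argmin([a / per_block for a in areas]))
                others = np.zeros(grid.shape, bool)
                for m, b in enumerate(blocks):
                    if m != k:
                        others |= b
                allowed = ~_dilate8(others)
                areas[k] += _grow_block(grid, blocks[k], allowed, rng)
        except WorldGenerationError:
            continue
        land = np.zeros(grid.shape, bool)
        for b in blocks:
            land |= b
        if count_components(land) != n_blocks:
            continue
        return grid.with_mask(land, basalt_fraction)
    raise WorldGenerationError(
        f"could not place {n_blocks} disjoint blocks with land_fraction={land_fraction}")


# ---------------------------------------------------------------------------
# forcing and climate synthesis
# ---------------------------------------------------------------------------

@dataclass
class ForcingState:
    """Scalar boundary conditions: geologic time, O2, relative degassing."""

    time_Ma: float = 0.0
    o2_mixing_ratio: float = 0.21
    degassing_rel: float = 1.0

    def __post_init__(self) -> None:
        if self.time_Ma < 0:
            raise ValueError("time_Ma must be >= 0")
        if not 0.05 <= self.o2_mixing_ratio <= 0.40:
            raise ValueError("o2_mixing_ratio must lie in [0.05, 0.40]")
        if self.degassing_rel <= 0:
            raise ValueError("degassing_rel must be > 0")


@dataclass
class ClimateField:
    """Annual-mean temperature (degC), runoff (mm/yr) and relative insolation."""

    temperature: np.ndarray
    runoff: np.ndarray
    insolation_rel: np.ndarray


@dataclass
class ClimateParams:
    """Shape constants of the synthetic climate.

    Temperature is a zonal profile ``t_eq - dt_pole*sin^2(lat)`` minus a
    continentality cooling that deepens with coast distance, plus a
    polar-amplified global offset.  Runoff follows a zonal wetness profile
    (wet equator, dry subtropics near \\|lat\\| 15-35 deg, wetter
    mid-latitudes) damped exponentially with coast distance; interiors
    beyond ``d_arid`` steps from the coast, and any cell below
    ``runoff_floor``, are fully arid (runoff 0).  A warming offset scales
    runoff by ``1 + hydro_sensitivity * offset``.
    """

    t_eq: float = 27.0            # degC at the equator
    dt_pole: float = 45.0         # equator-to-pole contrast, degC
    interior_cooling: float = 0.8  # degC per BFS step inland
    interior_cooling_max: float = 8.0
    polar_amp_max: float = 2.0    # offset amplification factor at the poles
    runoff_lat_nodes: tuple = (0.0, 10.0, 18.0, 32.0, 42.0, 58.0, 75.0, 90.0)
    runoff_lat_values: tuple = (1500.0, 1500.0, 150.0, 150.0, 700.0, 700.0, 300.0, 60.0)
    interior_efold: float = 3.0   # cells
    d_arid: int = 6               # coast distance beyond which interiors are arid
    runoff_floor: float = 40.0    # mm/yr; below this runoff snaps to zero
    hydro_sensitivity: float = 0.03  # fractional runoff change per degC offset

    def __post_init__(self) -> None:
        if self.interior_efold <= 0:
            raise ValueError("interior_efold must be > 0")
        if self.d_arid < 1:
            raise ValueError("d_arid must be >= 1")
        if len(self.runoff_lat_nodes) != len(self.runoff_lat_values):
            raise ValueError("runoff profile nodes and values differ in length")


def synth_climate(grid: WorldGrid, forcing: ForcingState,
                  gast_offset: float = 0.0,
                  params: ClimateParams | None = None) -> ClimateField:
    """Synthesise a gridded annual climate for a world and global offset.

    ``gast_offset`` is the global average surface temperature anomaly
    relative to the reference climate; it is applied with linear polar
    amplification (factor 1 at the equator rising to ``polar_amp_max`` at
    the poles) and nudges the hydrological cycle.
    """
    from .vegetation import insolation_factor

    p = params or ClimateParams()
    lat = grid.lat2d
    alat = np.abs(lat)
    dist = grid.coast_distance()

    temp = p.t_eq - p.dt_pole * np.sin(np.radians(lat)) ** 2
    cooling = np.minimum(p.interior_cooling * np.maximum(dist - 1, 0),
                         p.interior_cooling_max)
    temp = temp - np.where(grid.land_mask, cooling, 0.0)
    amp = 1.0 + (p.polar_amp_max - 1.0) * alat / 90.0
    temp = temp + amp * gast_offset

    zonal = np.interp(alat, p.runoff_lat_nodes, p.runoff_lat_values)
    decay = np.exp(-np.maximum(dist - 1, 0) / p.interior_efold)
    runoff = zonal * decay * max(0.0, 1.0 + p.hydro_sensitivity * gast_offset)
    runoff = np.where(grid.land_mask, runoff, 0.0)
    runoff = np.where(dist >= p.d_arid, 0.0, runoff)
    runoff = np.where(runoff < p.runoff_floor, 0.0, runoff)

    insol = insolation_factor(lat, forcing.time_Ma)
    return ClimateField(temperature=temp, runoff=runoff, insolation_rel=insol)


# ---------------------------------------------------------------------------
# IO: netCDF (scipy engine) and long-format CSV
# ---------------------------------------------------------------------------

_NC_VARS = ("temperature_C", "runoff_mm_yr", "land_mask", "basalt_fraction")


def world_to_dataset(grid: WorldGrid, climate: ClimateField) -> xr.Dataset:
    return xr.Dataset(
        {
            "temperature_C": (("lat", "lon"), climate.temperature),
            "runoff_mm_yr": (("lat", "lon"), climate.runoff),
            "land_mask": (("lat", "lon"), grid.land_mask.astype(np.int8)),
            "basalt_fraction": (("lat", "lon"), grid.basalt_fraction),
        },
        coords={"lat": grid.lat_centers, "lon": grid.lon_centers},
    )


def save_world(path: str | Path, grid: WorldGrid, climate: ClimateField) -> None:
    """Write a world + climate to netCDF (.nc) or long-format CSV (.csv)."""
    path = Path(path)
    if path.suffix == ".csv":
        lat2d = grid.lat2d
        lon2d = np.broadcast_to(grid.lon_centers[None, :], grid.shape)
        pd.DataFrame({
            "lat": lat2d.ravel(),
            "lon": lon2d.ravel(),
            "temperature_C": climate.temperature.ravel(),
            "runoff_mm_yr": climate.runoff.ravel(),
            "land": grid.land_mask.ravel().astype(int),
            "basalt_fraction": grid.basalt_fraction.ravel(),
        }).to_csv(path, index=False)
    else:
        world_to_dataset(grid, climate).to_netcdf(path, engine="scipy")


def load_climate(path: str | Path, var_map: dict[str, str] | None = None,
                 time_Ma: float = 0.0) -> tuple[WorldGrid, ClimateField]:
    """Load a (grid, climate) pair written by :func:`save_world`.

    ``var_map`` renames file variables to the canonical names.  Relative
    insolation is recomputed from latitude and ``time_Ma`` (it is a pure
    function of both, so it is not stored).  Raises ``ValueError`` naming
    the first missing variable, and rejects negative runoff.
    """
    path = Path(path)
    var_map = var_map or {}
    if path.suffix == ".csv":
        df = pd.read_csv(path).rename(columns=var_map)
        for col in ("lat", "lon", "temperature_C", "runoff_mm_yr", "land"):
            if col not in df.columns:
                raise ValueError(f"missing variable '{col}' in {path.name}")
        lats = np.sort(df["lat"].unique())
        lons = np.sort(df["lon"].unique())
        grid = make_grid(len(lats), len(lons))
        df = df.sort_values(["lat", "lon"])
        if len(df) != grid.n_lat * grid.n_lon:
            raise ValueError("CSV rows do not form a complete lat-lon grid")
        shape = grid.shape
        temp = df["temperature_C"].to_numpy().reshape(shape)
        runoff = df["runoff_mm_yr"].to_numpy().reshape(shape)
        land = df["land"].to_numpy().reshape(shape).astype(bool)
        if "basalt_fraction" in df.columns:
            bf = df["basalt_fraction"].to_numpy().reshape(shape)
        else:
            bf = 0.25
    else:
        ds = xr.open_dataset(path, engine="scipy").rename(var_map)
        for name in _NC_VARS[:3]:
            if name not in ds:
                raise ValueError(f"missing variable '{name}' in {path.name}")
        grid = make_grid(ds.sizes["lat"], ds.sizes["lon"])
        temp = ds["temperature_C"].values
        runoff = ds["runoff_mm_yr"].values
        land = ds["land_mask"].values.astype(bool)
        bf = ds["basalt_fraction"].values if "basalt_fraction" in ds else 0.25
        ds.close()
    if temp.shape != grid.shape or runoff.shape != grid.shape:
        raise ValueError("variable shapes do not match the lat-lon grid")
    if np.nanmin(runoff) < 0:
        raise ValueError("runoff must be non-negative everywhere")
    grid = grid.with_mask(land, bf)
    from .vegetation import insolation_factor

    insol = insolation_factor(grid.lat2d, time_Ma)
    return grid, ClimateField(temperature=temp, runoff=runoff, insolation_rel=insol)
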