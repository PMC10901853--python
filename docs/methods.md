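# Methods

This note documents the model equations, the numerical choices, the
synthetic-data design, and the limits of what the package's tests can show.

## Model structure

The simulator couples three layers on an equal-angle lat–lon grid
(default 40 × 48; longitude periodic, latitude closed; cell areas from the
spherical band formula, so the grid total equals 4πR² exactly).

### Vegetation kernel

Per-cell NPP for each plant functional type (PFT) is a capped
multiplicative-limitation product:

    NPP = min(NPPmax, NPPmax · g_T · g_W · g_L · g_C · g_O · (1 − s))

- `g_T`: trapezoidal temperature ramp per PFT — tropical (2, 25, 30, 55) °C,
  temperate (−4, 15, 25, 38) °C, boreal (−4, 10, 25, 38) °C (LPJ-heritage
  limits, all overridable). Zero outside [t_min, t_max].
- `g_W = runoff / (runoff + 30 mm yr⁻¹)`: saturating water response; the
  half-saturation is deliberately small so wet tropics are not water-limited.
- `g_L`: relative insolation, cos(latitude) × past solar luminosity
  `1/(1 + 0.4·t/4570)` (t in Myr), normalised to 1 at the present-day
  equator (~4.5% dimmer at 541 Ma).
- `g_C = RCO₂(1 + k)/(RCO₂ + k)` with `k = 0.5`: saturating CO₂
  fertilisation normalised to 1 at RCO₂ = 1 (asymptote 1.5).
- `g_O = clamp(1 − 0.3·(O₂mr − 0.21)/0.21, 0, 1.1)`: mild photorespiration
  penalty, exactly 1 at present-day oxygen.
- `s = (24/h)·a` with `h = 12` daylight hours (no seasonality) and
  `a = 0.015`. `a` is a free parameter of this kernel; only `h` is pinned by
  the model design.

`NPPmax = 3200 gC m⁻² yr⁻¹` is the unique value for which the weathering
enhancement law below gives exactly a 6-fold ceiling-to-bare-ground ratio at
RCO₂ = 1 (0.0005·3200 + 0.32 = 6 × 0.32).

Cells with zero runoff or annual temperature < −10 °C are uninhabitable and
hard-zeroed before any iteration. The dominant PFT per cell is the argmax
of NPP with fixed tie priority tropical > temperate > boreal.

Biomass follows the annual recurrence `B ← B + NPP − τB` from a uniform
colonisation seed of 2.5 × 10⁴ gC m⁻² (vegetation is re-established from
scratch at every carbon-cycle step), with fire-driven turnover

    τ = min(max(0.0092·(100·O₂mr − 10), 0.08), 0.2)

which doubles between present-day oxygen (τ ≈ 0.101) and its cap. NPP does
not depend on standing biomass (no self-shading), so the fixed point is
exactly `B* = NPP/τ`.

**Convergence norm.** The iteration stops when the turnover-normalised
annual change `|ΔB|/(τB)` falls below `tol = 0.01` in every habitable cell.
Because `ΔB = τ(B* − B)`, this criterion *is* the relative distance to the
fixed point, so the returned biomass is guaranteed within tol of `NPP/τ`
and the iteration count is the analytic solution of the geometric
recurrence. A plain successive-change norm would only bound the error by
tol/τ (up to 12.5× looser at τ = 0.08), which would make the accuracy of
the returned field depend on the oxygen state; the normalised form keeps
the accuracy contract independent of τ.

### Weathering

Per-cell biotic enhancement (the coupling quantity):

    f_biota = 0.0005·NPP + 0.32·RCO₂^r,   r = 0.25

applied to every cell; at NPP = 0 it reduces to the GEOCARB-style abiotic
pH term, so no separate "uncolonised" branch is needed. `r` is held at the
conservative end of its 0.25–0.5 range.

Silicate flux per cell:

    F_sil = A · q · f_biota · Σ_lith frac_lith · k_lith · exp[(E_lith/R)(1/288.15 − 1/T)]

with activation energies 63 (granite) and 50 (basalt) kJ mol⁻¹ and runoff q
in mm yr⁻¹; carbonate flux shares the `A·q·f_biota` kernel with a single
rate constant. These kinetics are standard spatially-resolved
weathering-model plumbing, not a contribution of this package; erosion
dependence is folded into the rate constants. Land organic burial is
`k_locb · v_rel` where `v_rel` is global biomass relative to the
calibration baseline; marine burial is constant.

### Carbon cycle and coupling

One lumped atmosphere–ocean inventory C with `RCO₂ = C/C_ref`
(C_ref = 3.2 × 10¹⁸ mol) and

    dC/dt = degassing_rel·F_degas − F_sil − B_locb − B_mocb

(F_degas = 8 × 10¹² mol yr⁻¹; carbonate weathering is carbon-neutral on
this timescale and closed as deposition). GAST = 14 °C + 5 °C·log₂(RCO₂);
both the sensitivity and the reference temperature are config-exposed and
order-of-magnitude deep-time values, not fitted quantities.

Each coupled step: (1) synthesise the climate at the current GAST anomaly;
(2) re-seed and spin the vegetation kernel; (3) evaluate f_biota, global
fluxes and burial; (4) advance C by explicit Euler. The timestep starts at
10⁵ yr and adapts: it halves (down to 10³ yr) whenever the step would move
RCO₂ by more than 2%, grows by 1.2× (up to 10⁶ yr) otherwise, and also
halves whenever the tendency changes sign between steps. The sign-flip rule
matters: near equilibrium the 2% step limiter alone admits a stable
small-amplitude limit cycle of the explicit scheme (the system's relaxation
time ~2 × 10⁵ yr is shorter than the maximum step), and halving on
oscillation collapses it deterministically. Steady state is declared at
|dC/dt| < 10⁻⁴·F_degas; RCO₂ leaving [0.01, 16] is a hot/cold runaway, and
loss of all habitable area away from balance is an extinction — both are
recorded outcomes, not exceptions.

**Calibration.** Rate constants are scaled once so that a chosen reference
world at RCO₂ = 1 balances reference degassing with sink shares 80%
silicate / 10% land burial / 10% marine burial, and `v_rel = 1` there. In
multi-world experiments the constants must be shared for the comparison to
be meaningful: `compare-worlds` calibrates on world_b (by convention the
dispersed/reference configuration); ensembles calibrate on the ensemble
world at reference forcing. The calibration is idempotent and fails loudly
on a world with no weatherable flux.

## Synthetic worlds

The generators emulate the boundary conditions a GCM emulator would supply,
not any real paleogeography.

- **Supercontinent**: seeded compactness-weighted accretion from a chosen
  central latitude; one 4-connected block (longitude-periodic), total area
  within one cell of the target fraction.
- **Dispersed**: n blocks grown round-robin from seeds spread evenly in
  longitude at latitudes jittered ±20° around a central latitude, kept ≥1
  ocean cell apart. The longitude-stratified placement is deliberate: a
  fragmentation series (n = 1, 2, 3, …) then varies geographic range while
  holding the latitudinal land distribution roughly fixed, which is the
  control needed to isolate the range → weathering mechanism from the
  (strong) dependence of weathering on where land sits in the zonal climate.
- **Climate**: temperature `27 − 45·sin²(lat)` °C minus continental-interior
  cooling (0.8 °C per coast-distance step, capped at 8 °C) plus the GAST
  anomaly with linear polar amplification (×1 equator → ×2 pole). Runoff is
  a zonal profile (1500 mm yr⁻¹ equatorial peak, 150 in the 15–35°
  subtropical belts, 700 at mid-latitudes) damped as exp(−(d−1)/3) in coast
  distance d, scaled by (1 + 0.03·ΔGAST); interiors at d ≥ 6 and any value
  below 40 mm yr⁻¹ are fully arid. The hard aridity cap is what produces
  contiguous zero-runoff interiors on supercontinents — the geometry the
  range mechanism depends on — rather than merely low runoff.

Runoff magnitudes are calibrated only to produce plausible habitability
fractions (dispersed worlds ~90–100% habitable, supercontinents ~65–75%);
they are not tied to any GCM product. The synthetic worlds have no
seasonality, no orography, no precipitation/evaporation partitioning and no
continental drift within a run, so passing tests demonstrate the internal
mechanism under controlled geography — not skill against real
paleoclimate data.

## Experiment sizes

The shipped experiments use the 40 × 48 grid throughout: single steady
states take tens of coupled steps (well under a second), the five-world
fragmentation series and the 20-member ensemble run in a few seconds, and
the whole test suite in well under a minute.

## Known limitations

- No colonisation/dispersal dynamics, biome turnover, or biomass carry-over
  between carbon-cycle steps (re-seeding is by design).
- No P, S, O₂ feedback or isotope systems; marine burial fixed; carbonate
  weathering has no climate role beyond its diagnostic flux.
- One lumped carbon reservoir; no ocean chemistry or carbonate compensation.
- The CO₂→GAST map and the degassing/reservoir scales are literature-order
  constants; absolute CO₂ levels are therefore only meaningful relative to
  the calibrated reference, which is why results are reported as RCO₂.
- Uniform lithology (default basalt fraction 0.25 on land) unless varied by
  the ensemble or a user mask.
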