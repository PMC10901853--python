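# vegrange

**How the geographic range of land plants steers silicate weathering and
long-term atmospheric CO₂.**

`vegrange` is a desk-scale coupled simulator for exploring a central
mechanism of deep-time climate regulation: vegetation amplifies chemical
weathering of silicate rock, weathering consumes CO₂, and the *area* over
which plants grow — not just their total biomass — therefore controls where
the long-term carbon cycle balances. A compact supercontinent develops vast
arid interiors that exclude plants, shrinking the weathering-enhanced area
and letting CO₂ settle at a higher steady state than on dispersed continents
of identical total land area.

The package couples three components on a lat–lon grid (default 40 × 48):

1. **A gridded vegetation kernel.** Per-cell net primary productivity for
   three plant functional types (tropical, temperate, boreal) as a capped
   multiplicative-limitation product
   `NPP = min(NPPmax, NPPmax · g_T g_W g_L g_C g_O (1 − s))`, with leaf
   respiration `s = (24/h)·a`. Standing biomass follows the annual
   recurrence `B ← B + NPP − B_turnover·B` from a uniform colonisation seed
   of 2.5 × 10⁴ gC m⁻², where fire-driven turnover rises with oxygen:
   `B_turnover = min(max(0.0092·(100·O₂mr − 10), 0.08), 0.2)`.
   Cells with no runoff or annual temperature below −10 °C carry no
   vegetation.

2. **Per-cell weathering.** The biotic enhancement factor
   `f_biota = 0.0005·NPP + 0.32·RCO₂^0.25`
   multiplies runoff-linear, Arrhenius-temperature silicate and carbonate
   weathering kinetics split between basaltic and granitic lithology. At the
   NPP ceiling the enhancement is exactly 6-fold over bare ground.

3. **A lumped long-term carbon cycle.** One atmosphere–ocean inventory with
   `dC/dt = degassing − silicate weathering − organic burial`, a logarithmic
   CO₂→temperature map, and an adaptive ~100 kyr explicit timestep. Every
   step re-seeds the vegetation kernel, spins it to steady state (<1%
   change), and feeds NPP and global biomass back into weathering and
   burial. Runs converge to a steady state or end in a classified failure
   (runaway hot/cold climate, vegetation extinction) — failures are data.

Synthetic worlds (supercontinent vs dispersed land masks with zonal
temperature, subtropical dry belts and arid continental interiors) stand in
for GCM-derived boundary conditions, so every experiment runs in seconds on
a laptop with no external data. User-supplied climate grids load from
netCDF or CSV. An ensemble driver varies degassing and lithology across
members to build uncertainty envelopes, tolerating runaway members.

## Worked example

Compare a supercontinent against four dispersed continents of identical
total land area under identical forcing:

```sh
vegrange compare-worlds -c configs/demo_compare.yaml
```

```
             metric      world_a      world_b    difference  sign
 habitable_fraction 7.106250e-01 9.785045e-01 -2.678795e-01    -1
        steady_rco2 3.119522e+00 1.000000e+00  2.119522e+00     1
             gast_C 2.220662e+01 1.400000e+01  8.206625e+00     1
total_silicate_flux 6.545159e+12 6.400000e+12  1.451588e+11     1
```

world_a is the supercontinent, world_b the dispersed reference on which the
weathering rate constants were calibrated. Only 71% of the supercontinent
can host plants (its subtropical interior is arid), versus 98% of the
dispersed land. With less area under biotic weathering enhancement, the
carbon cycle balances at 3.1× the reference CO₂ level and a global mean
surface temperature 8.2 °C warmer — same land, same volcanism, different
geography. The silicate flux column shows both worlds ultimately consume
(nearly) the same CO₂ flux at steady state: what differs is the CO₂ level
required to achieve it.

The same comparison through the library:

```python
import vegrange as vr

grid = vr.make_grid(40, 48)
superc = vr.make_supercontinent(grid, land_fraction=0.3, seed=1)
dispersed = vr.make_dispersed(grid, land_fraction=0.3, n_blocks=4, seed=1)

params = vr.calibrate_reference(dispersed, vr.ModelParams(), vr.CouplerConfig())
forcing = vr.ForcingState(o2_mixing_ratio=0.21, degassing_rel=1.0)
result = vr.run_to_steady(superc, forcing, params)
print(result.failure_mode, result.steady_rco2)   # none 3.119...
```

Other entry points: `vegrange simulate` (one world to steady state, with a
trajectory CSV and a gridded netCDF snapshot), `vegrange ensemble`
(parameter sensitivity with quantile envelopes), `vegrange make-world` and
`vegrange validate-config`. Every run emits its fully resolved config, from
which it can be replayed byte-identically.

## Layout

- `src/vegrange/worlds.py` — grids, land-mask generators, synthetic climate, IO
- `src/vegrange/vegetation.py` — NPP kernel, turnover, steady-state biomass
- `src/vegrange/weathering.py` — enhancement law, weathering kinetics, burial
- `src/vegrange/carbon.py` — carbon reservoir, calibration, coupled driver
- `src/vegrange/ensemble.py` — sensitivity ensembles
- `src/vegrange/config.py`, `src/vegrange/cli.py` — YAML configs and the CLI
- `docs/methods.md` — model description, parameter rationale, limitations
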