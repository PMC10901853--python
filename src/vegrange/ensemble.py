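"""Parameter-ensemble driver for sensitivity analysis.

Reproduces the protocol of varying relative degassing and the
basaltic/granitic lithology split (an absolute shift of the basalt fraction,
+-0.2, clamped to [0, 1]) across independently-run members, tolerating
member failures (e.g. runaway climates) and summarising successful members
with 2.5/50/97.5% quantile envelopes.  Optional ``extra_ranges`` hooks vary
parameters that exist in this reduced model (``f_minbiota``,
``climate_sensitivity``), standing in for isotope-fractionation axes that
carry no state here.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .carbon import CouplerConfig, ModelParams, RunResult, run_to_steady
from .worlds import ForcingState, WorldGrid

__all__ = ["EnsembleSpec", "MemberParams", "EnsembleResult",
           "sample_params", "run_ensemble"]

_SUPPORTED_EXTRAS = ("f_minbiota", "climate_sensitivity")
_ENVELOPE_COLS = ("steady_rco2", "gast_C", "habitable_fraction", "v_rel")
_QUANTILES = (0.025, 0.5, 0.975)


@dataclass
class EnsembleSpec:
    """Sampling design: member count, parameter intervals, RNG seed."""

    n_members: int
    degassing_range: tuple[float, float] = (0.75, 1.25)
    lithology_shift: tuple[float, float] = (-0.2, 0.2)
    extra_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        for name, (lo, hi) in [("degassing_range", self.degassing_range),
                               ("lithology_shift", self.lithology_shift),
                               *self.extra_ranges.items()]:
            if lo > hi:
                raise ValueError(f"interval {name} is not well-ordered")
        for name in self.extra_ranges:
            if name not in _SUPPORTED_EXTRAS:
                raise ValueError(
                    f"unsupported extra range '{name}'; supported: {_SUPPORTED_EXTRAS}")


@dataclass
class MemberParams:
    """One sampled parameter set."""

    member_id: int
    degassing_rel: float
    basalt_shift: float
    extras: dict[str, float] = field(default_factory=dict)


def sample_params(spec: EnsembleSpec) -> list[MemberParams]:
    """Independent uniform draws per member; deterministic under rng_seed."""
    rng = np.random.default_rng(spec.rng_seed)
    members = []
    extra_names = sorted(spec.extra_ranges)
    for i in range(spec.n_members):
        deg = rng.uniform(*spec.degassing_range)
        shift = rng.uniform(*spec.lithology_shift)
        extras = {name: float(rng.uniform(*spec.extra_ranges[name]))
                  for name in extra_names}
        members.append(MemberParams(i, float(deg), float(shift), extras))
    return members


@dataclass
class EnsembleResult:
    """Per-member summaries, success count and quantile envelope."""

    members: pd.DataFrame          # one row per member
    runs: list[RunResult]
    n_success: int
    envelope: pd.DataFrame | None  # quantiles over successful members, or None
    all_failed: bool


def _apply_member(member: MemberParams, world: WorldGrid,
                  forcing: ForcingState, params: ModelParams,
                  config: CouplerConfig
                  ) -> tuple[WorldGrid, ForcingState, ModelParams, CouplerConfig]:
    bf = np.clip(world.basalt_fraction + member.basalt_shift, 0.0, 1.0)
    w = world.with_mask(world.land_mask, np.where(world.land_mask, bf, 0.0))
    f = dataclasses.replace(forcing, degassing_rel=member.degassing_rel)
    p, c = params, config
    if "f_minbiota" in member.extras:
        p = dataclasses.replace(
            p, weathering=dataclasses.replace(
                p.weathering, f_minbiota=member.extras["f_minbiota"]))
    if "climate_sensitivity" in member.extras:
        c = dataclasses.replace(
            c, climate_sensitivity=member.extras["climate_sensitivity"])
    return w, f, p, c


def run_ensemble(spec: EnsembleSpec, world: WorldGrid, forcing: ForcingState,
                 params: ModelParams, config: CouplerConfig | None = None,
                 members: list[MemberParams] | None = None) -> EnsembleResult:
    """Run all members independently; failures are recorded, never raised.

    ``params`` must already be calibrated (shared rate constants across
    members).  ``members`` overrides the sampled design, e.g. to replay a
    stored member or to inject a deliberately pathological one.  With zero
    successful members the result is flagged (``all_failed``), not raised.
    """
    config = config or CouplerConfig()
    if members is None:
        members = sample_params(spec)
    rows = []
    runs: list[RunResult] = []
    for m in members:
        w, f, p, c = _apply_member(m, world, forcing, params, config)
        res = run_to_steady(w, f, p, c)
        runs.append(res)
        last = res.trajectory.iloc[-1] if len(res.trajectory) else None
        rows.append({
            "member_id": m.member_id,
            "degassing_rel": m.degassing_rel,
            "basalt_shift": m.basalt_shift,
            **{f"extra_{k}": v for k, v in sorted(m.extras.items())},
            "success": res.success,
            "failure_mode": res.failure_mode,
            "steady_rco2": res.final_state.rco2 if res.success else np.nan,
            "gast_C": res.final_state.gast if res.success else np.nan,
            "habitable_fraction": (last["habitable_fraction"]
                                   if last is not None else np.nan),
            "v_rel": last["v_rel"] if last is not None else np.nan,
        })
    df = pd.DataFrame(rows)
    ok = df[df["success"]]
    n_success = int(len(ok))
    if n_success:
        env = pd.DataFrame(
            {col: np.quantile(ok[col].to_numpy(), _QUANTILES)
             for col in _ENVELOPE_COLS},
            index=[f"q{q}" for q in _QUANTILES])
    else:
        env = None
    return EnsembleResult(members=df, runs=runs, n_success=n_success,
                          envelope=env, all_failed=(n_success == 0))
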