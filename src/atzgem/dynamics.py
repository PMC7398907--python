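"""Time-stepped dynamic growth and substrate-depletion simulation.

The simulator iterates FBA over discrete time ticks under four assumptions:
(1) the medium holds finite starting pools of each component; (2) a single
biomass unit can take up at most ``uptake_cap`` units of any one metabolite
per tick (applied as the exchange lower bound); (3) each tick's pools are
the previous pools plus whatever was secreted minus whatever was consumed;
(4) after each tick the biomass is updated from the realized biomass flux.
The run stops once a tick no longer increases biomass (relative gain below
``stall_tol``) or at ``max_cycles``.

Pools are in the same dimensionless "units" as the uptake cap; the default
configuration (pools of 50 units, cap 1, one initial biomass unit, dt = 1 h)
matches the conditions the screening analyses assume.  Pool division —
the per-cell bound is ``min(cap, pool / (X dt))`` — guarantees a pool can
never be overdrawn, so pools stay non-negative by construction.  Secreted
products (e.g. cyanuric acid from atrazine degradation, or ammonium) are
credited to their pools and may be re-consumed in later ticks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .core import Media, MetabolicModel, apply_media
from .fba import solve_fba

__all__ = ["DynamicConfig", "Trajectory", "compute_uptake_bounds",
           "simulate_timecourse", "degradation_curve"]


@dataclass
class DynamicConfig:
    """Simulation parameters (all positive; ``stall_tol`` in (0, 1)).

    ``initial_pools`` maps exchange ids to starting amounts; ``math.inf``
    marks a non-depletable component (mineral ions).  Exchanges not listed
    start at 0: closed for uptake, but open to accumulate secretions.
    """

    initial_pools: dict[str, float] = field(default_factory=dict)
    dt: float = 1.0
    uptake_cap: float = 1.0
    #: per-exchange overrides of ``uptake_cap`` (e.g. to leave water and
    #: protons unthrottled; they are bookkeeping species, not nutrients)
    uptake_caps: dict[str, float] = field(default_factory=dict)
    initial_biomass: float = 1.0
    max_cycles: int = 200
    stall_tol: float = 1e-6
    #: exponential biomass update X * exp(mu dt) instead of forward Euler
    exponential_update: bool = False

    def __post_init__(self):
        if self.dt <= 0 or self.uptake_cap <= 0 or self.initial_biomass <= 0:
            raise ValueError("dt, uptake_cap and initial_biomass must be positive")
        if not 0 < self.stall_tol < 1:
            raise ValueError(f"stall_tol must be in (0, 1), got {self.stall_tol}")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        for ex_id, amount in self.initial_pools.items():
            if amount < 0:
                raise ValueError(f"initial pool for {ex_id!r} is negative")


@dataclass
class Trajectory:
    """Per-tick record of time, biomass, growth rate, pools and fluxes."""

    times: list[float]
    biomass: list[float]
    growth_rates: list[float]  # mu realized over the tick ending at times[i]
    pools: list[dict[str, float]]
    exchange_fluxes: list[dict[str, float]]
    stalled: bool

    @property
    def final_biomass(self) -> float:
        return self.biomass[-1]

    @property
    def n_ticks(self) -> int:
        return len(self.times) - 1

    def pool_series(self, exchange_id: str) -> list[float]:
        if exchange_id not in self.pools[0]:
            raise KeyError(f"exchange {exchange_id!r} not tracked in trajectory")
        return [p[exchange_id] for p in self.pools]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.times):
            row = {"time": t, "biomass": self.biomass[i],
                   "growth_rate": self.growth_rates[i]}
            row.update({f"pool:{k}": v for k, v in self.pools[i].items()})
            rows.append(row)
        return pd.DataFrame(rows)


def compute_uptake_bounds(pools: dict[str, float], biomass: float,
                          config: DynamicConfig) -> Media:
    """Per-cell uptake bounds for one tick: ``min(cap, pool / (X dt))``.

    Exhausted pools give a zero bound; infinite pools give the cap.
    """
    if biomass <= 0:
        raise ValueError(f"biomass must be positive, got {biomass}")
    uptakes = {}
    for ex_id, pool in pools.items():
        if pool < 0:
            raise AssertionError(f"negative pool for {ex_id!r}: {pool}")
        cap = config.uptake_caps.get(ex_id, config.uptake_cap)
        if math.isinf(pool):
            uptakes[ex_id] = cap
        else:
            uptakes[ex_id] = min(cap, pool / (biomass * config.dt))
    return Media(uptakes=uptakes, name="dynamic-tick")


def simulate_timecourse(model: MetabolicModel,
                        config: DynamicConfig) -> Trajectory:
    """Run the tick loop until biomass stalls or ``max_cycles`` is reached.

    Each tick: set exchange bounds from the current pools and biomass, solve
    FBA, debit/credit the pools with the realized exchange fluxes times
    ``X dt``, and grow the biomass by ``X (1 + mu dt)`` (or ``X exp(mu dt)``
    with the exponential option).  An infeasible tick records mu = 0 and
    falls through to the termination test.
    """
    model.validate()
    exchange_ids = [r.id for r in model.exchanges]
    # pool entries for exchanges the model lacks are ignored: pool
    # definitions, like media, are organism-independent
    pools = {ex: float(config.initial_pools.get(ex, 0.0)) for ex in exchange_ids}
    X = float(config.initial_biomass)
    dt = config.dt

    times = [0.0]
    biomass = [X]
    growth_rates = [0.0]
    pool_hist = [dict(pools)]
    flux_hist: list[dict[str, float]] = [{ex: 0.0 for ex in exchange_ids}]
    stalled = False

    for cycle in range(1, config.max_cycles + 1):
        media = compute_uptake_bounds(pools, X, config)
        sol = solve_fba(apply_media(model, media))
        mu = sol.objective_value if sol.optimal else 0.0

        realized = {}
        for ex in exchange_ids:
            v = sol.fluxes.get(ex, 0.0) if sol.optimal else 0.0
            realized[ex] = v
            if not math.isinf(pools[ex]):
                pools[ex] = max(0.0, pools[ex] + v * X * dt)

        X_new = X * math.exp(mu * dt) if config.exponential_update \
            else X * (1.0 + mu * dt)

        times.append(cycle * dt)
        biomass.append(X_new)
        growth_rates.append(mu)
        pool_hist.append(dict(pools))
        flux_hist.append(realized)

        if (X_new - X) / X < config.stall_tol:
            stalled = True
            X = X_new
            break
        X = X_new

    return Trajectory(times=times, biomass=biomass, growth_rates=growth_rates,
                      pools=pool_hist, exchange_fluxes=flux_hist, stalled=stalled)


def degradation_curve(trajectory: Trajectory,
                      target: str) -> list[tuple[float, float]]:
    """(time, amount remaining) for a consumed substrate.

    For a pure substrate (never secreted) the series is monotone
    non-increasing; once exhausted the tail is constant zero.
    """
    series = trajectory.pool_series(target)
    return list(zip(trajectory.times, series))
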