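"""Flux balance analysis and flux variability analysis.

FBA maximizes the biomass objective subject to the steady-state constraint
S v = 0 (boundary species excluded) and the reaction flux bounds.  FVA then
re-optimizes each reaction of interest in both directions with the biomass
flux held at (a fraction of) its optimum.

Only the objective value and FVA ranges are contract-stable: the flux vector
of a large network is generally degenerate, so individual fluxes should not
be relied upon unless FVA shows them forced (min == max).

All linear programs go through one backend function built on
``scipy.optimize.linprog`` (HiGHS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .core import Media, MetabolicModel, apply_media, build_stoichiometric_matrix

__all__ = [
    "FEASIBILITY_TOL",
    "FluxSolution",
    "FvaResult",
    "solve_fba",
    "run_fva",
    "degradation_capacity",
]

#: Primal feasibility tolerance requested from the solver and used when
#: interpreting near-zero objective values.
FEASIBILITY_TOL = 1e-9


@dataclass
class FluxSolution:
    """Result of one FBA solve."""

    objective_value: float
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded
    tolerance: float = FEASIBILITY_TOL

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class FvaResult:
    """Per-reaction (min, max) flux at a fixed objective level."""

    ranges: dict[str, tuple[float, float]]
    objective_value: float
    objective_fraction: float = 1.0

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]

    def __iter__(self):
        return iter(self.ranges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(rid, lo, hi) for rid, (lo, hi) in self.ranges.items()],
            columns=["reaction_id", "min_flux", "max_flux"],
        )


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded"}


def _maximize(c: np.ndarray, A_eq: sparse.spmatrix, bounds: list[tuple[float, float]],
              A_ub: sparse.spmatrix | None = None,
              b_ub: np.ndarray | None = None) -> tuple[str, float, np.ndarray]:
    """Maximize c.v subject to A_eq v = 0, optional A_ub v <= b_ub, bounds."""
    res = linprog(
        -c,
        A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]),
        A_ub=A_ub, b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
    )
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return status, 0.0, np.zeros(len(c))
    return status, -res.fun, res.x


def _lp_parts(model: MetabolicModel):
    matrix = build_stoichiometric_matrix(model)
    keep = [i for i, mid in enumerate(matrix.row_ids)
            if not model.metabolite(mid).boundary]
    A_eq = matrix.S[keep, :] if keep else sparse.csr_matrix((0, len(matrix.col_ids)))
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    col_index = {rid: j for j, rid in enumerate(matrix.col_ids)}
    return A_eq, bounds, matrix.col_ids, col_index


def solve_fba(model: MetabolicModel, media: Media | None = None) -> FluxSolution:
    """Maximize the biomass objective; see module docs for the formulation.

    An infeasible problem returns ``status='infeasible'`` with zero fluxes;
    an unbounded one returns ``status='unbounded'`` (a missing constraint,
    typically an exchange left open in both directions without limit).
    """
    if media is not None:
        model = apply_media(model, media)
    model.validate()
    A_eq, bounds, col_ids, col_index = _lp_parts(model)
    c = np.zeros(len(col_ids))
    c[col_index[model.objective_id]] = 1.0
    status, value, x = _maximize(c, A_eq, bounds)
    fluxes = {rid: float(x[j]) for j, rid in enumerate(col_ids)}
    return FluxSolution(objective_value=float(value), fluxes=fluxes, status=status)


def run_fva(model: MetabolicModel, media: Media | None = None,
            reaction_ids: list[str] | None = None,
            objective_fraction: float = 1.0) -> FvaResult:
    """Flux ranges with biomass constrained to >= fraction x its optimum.

    ``objective_fraction`` of 0 reduces to plain bounds propagation; 1 fixes
    the biomass at its maximum (up to the solver feasibility tolerance).
    """
    if not 0.0 <= objective_fraction <= 1.0:
        raise ValueError(f"objective_fraction must be in [0, 1], got {objective_fraction}")
    if media is not None:
        model = apply_media(model, media)
    base = solve_fba(model)
    if not base.optimal:
        raise RuntimeError(f"FVA requires an optimal base solution, got {base.status}")

    A_eq, bounds, col_ids, col_index = _lp_parts(model)
    n = len(col_ids)
    obj_row = sparse.lil_matrix((1, n))
    obj_row[0, col_index[model.objective_id]] = -1.0
    # biomass >= fraction * mu*, written as -v_biomass <= -target; the small
    # absolute slack keeps the fixed-biomass problem numerically feasible
    target = objective_fraction * base.objective_value
    b_ub = np.array([-(target - 1e-9 - abs(target) * 1e-9)])

    if reaction_ids is None:
        reaction_ids = list(col_ids)
    ranges: dict[str, tuple[float, float]] = {}
    for rid in reaction_ids:
        if rid not in col_index:
            raise KeyError(f"unknown reaction id {rid!r}")
        c = np.zeros(n)
        c[col_index[rid]] = 1.0
        extremes = []
        for sign in (-1.0, 1.0):
            status, value, _ = _maximize(sign * c, A_eq, bounds,
                                         A_ub=obj_row.tocsr(), b_ub=b_ub)
            if status != "optimal":
                raise RuntimeError(
                    f"FVA subproblem for {rid!r} at fraction {objective_fraction} "
                    f"is {status}")
            extremes.append(sign * value)
        lo, hi = min(extremes), max(extremes)
        ranges[rid] = (float(lo), float(hi))
    return FvaResult(ranges=ranges, objective_value=base.objective_value,
                     objective_fraction=objective_fraction)


def degradation_capacity(model: MetabolicModel, media: Media,
                         target_exchange: str) -> tuple[float, float]:
    """Uptake range (magnitudes) of ``target_exchange`` at the growth optimum.

    This is FVA restricted to the target exchange at objective fraction 1.0;
    with atrazine as the target it estimates the degradation rate compatible
    with maximal growth.  Returns ``(min_uptake, max_uptake)``, both >= 0.
    """
    constrained = apply_media(model, media)
    rxn = constrained.reaction(target_exchange)
    if rxn.rtype != "exchange":
        raise ValueError(f"{target_exchange!r} is not an exchange reaction")
    fva = run_fva(constrained, reaction_ids=[target_exchange], objective_fraction=1.0)
    lo, hi = fva[target_exchange]
    # uptake is negative exchange flux; convert to magnitudes
    return (max(0.0, -hi), max(0.0, -lo))
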