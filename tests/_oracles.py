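"""Independent oracles used by the test suite.

``vertex_optimum`` solves max c.v subject to S v = 0, l <= v <= u by brute
force: every vertex of the bounded polytope has n - rank(S) variables at a
bound, so all candidate bound patterns are enumerated and the remaining
square/overdetermined system solved directly.  It shares no code with the
package's LP path and is tractable only for small networks (<= ~10
reactions), which is exactly what it is for.

``to_cobra`` converts a model to a cobrapy model (solved with GLPK), giving
a second, fully independent FBA/FVA implementation for cross-checks.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from atzgem.core import MetabolicModel, build_stoichiometric_matrix

FEAS = 1e-8


def _lp_arrays(model: MetabolicModel):
    matrix = build_stoichiometric_matrix(model)
    keep = [i for i, mid in enumerate(matrix.row_ids)
            if not model.metabolite(mid).boundary]
    S = matrix.S.toarray()[keep, :]
    lower = np.array([r.lower_bound for r in model.reactions])
    upper = np.array([r.upper_bound for r in model.reactions])
    c = np.zeros(len(model.reactions))
    c[matrix.col_ids.index(model.objective_id)] = 1.0
    return S, lower, upper, c


def vertex_optimum(model: MetabolicModel) -> float:
    """Brute-force optimum of the biomass LP by vertex enumeration."""
    S, lower, upper, c = _lp_arrays(model)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if m else 0
    n_fixed = n - rank
    best = -np.inf
    for fixed in combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        S_free = S[:, free]
        for pattern in product((0, 1), repeat=n_fixed):
            x = np.zeros(n)
            for j, p in zip(fixed, pattern):
                x[j] = upper[j] if p else lower[j]
            rhs = -S[:, list(fixed)] @ x[list(fixed)] if fixed else np.zeros(m)
            if free:
                sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
                x[free] = sol
            if not np.allclose(S @ x, 0.0, atol=FEAS):
                continue
            if (x < lower - FEAS).any() or (x > upper + FEAS).any():
                continue
            best = max(best, float(c @ x))
    if best == -np.inf:
        raise RuntimeError("vertex oracle found no feasible vertex")
    return best


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (boundary species simply dropped: cobrapy
    has no steady-state row for species that are not in any constraint)."""
    import cobra

    cm = cobra.Model(model.id)
    boundary = {m.id for m in model.metabolites if m.boundary}
    cmets = {}
    for met in model.metabolites:
        if met.id in boundary:
            continue
        cmets[met.id] = cobra.Metabolite(
            met.id, formula=met.formula or None, compartment=met.compartment)
    reactions = []
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.id)
        cr.lower_bound = rxn.lower_bound
        cr.upper_bound = rxn.upper_bound
        reactions.append(cr)
    cm.add_reactions(reactions)
    for rxn in model.reactions:
        stoich = {cmets[mid]: coef for mid, coef in rxn.stoichiometry.items()
                  if mid not in boundary}
        cm.reactions.get_by_id(rxn.id).add_metabolites(stoich)
    cm.objective = model.objective_id
    return cm
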