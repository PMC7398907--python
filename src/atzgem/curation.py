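"""Model-refinement audits.

Four checks mirror the manual curation steps a reconstruction goes through
before it is trusted for simulation:

* elemental/charge balance of every internal reaction;
* the blocked-exchange test — with every exchange closed in both directions
  a sound network can make neither biomass nor free ATP (a nonzero optimum
  exposes a futile, energy-generating loop);
* the nutrient-requirement test — growth must vanish when all carbon or all
  nitrogen sources are withheld;
* a report-only directionality screen (reversible reactions whose reverse
  direction is never usable at the growth optimum).

Exchange reactions are by definition unbalanced (they move matter across the
system boundary) and the biomass pseudo-reaction produces a lumped cell
unit, so both are exempt from the balance tally.  Charge is tallied only
when every participant carries a charge annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import Media, MetabolicModel, Metabolite, Reaction, apply_media
from .fba import FEASIBILITY_TOL, run_fva, solve_fba
from .formulas import WILDCARD_TOKENS, parse_formula

__all__ = [
    "BALANCE_EXEMPT_RTYPES",
    "ElementTally",
    "AuditReport",
    "check_reaction_balance",
    "audit_model_balance",
    "blocked_exchange_audit",
    "nutrient_requirement_audit",
    "directionality_report",
]

BALANCE_EXEMPT_RTYPES = ("exchange", "biomass")

#: Biomass fluxes below this are treated as "no growth" in audits.
GROWTH_TOL = 1e-6


@dataclass
class ElementTally:
    """Signed per-element atom imbalance of one reaction.

    All-zero entries (and charge) mean the reaction is balanced.
    ``applicable`` is False for exempt reactions (exchange/biomass) and for
    reactions skipped because a participant has a wildcard formula.
    """

    imbalance: dict[str, float] = field(default_factory=dict)
    charge_imbalance: float | None = None
    applicable: bool = True

    @property
    def balanced(self) -> bool:
        if not self.applicable:
            return True
        if any(abs(v) > 1e-9 for v in self.imbalance.values()):
            return False
        return self.charge_imbalance is None or abs(self.charge_imbalance) <= 1e-9


@dataclass
class AuditReport:
    violations: list[tuple[str, ElementTally]]
    skipped: list[str]

    @property
    def passed(self) -> bool:
        return not self.violations

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rid, tally in self.violations:
            rows.append({
                "reaction_id": rid,
                "imbalance": "; ".join(f"{el}:{v:+g}" for el, v in
                                       sorted(tally.imbalance.items()) if v != 0),
                "charge_imbalance": tally.charge_imbalance,
            })
        return pd.DataFrame(rows, columns=["reaction_id", "imbalance", "charge_imbalance"])


class UnknownFormulaError(ValueError):
    pass


def check_reaction_balance(reaction: Reaction,
                           metabolites: dict[str, Metabolite]) -> ElementTally:
    """Tally = sum over participants of coefficient x atom counts.

    Exempt reaction types return an inapplicable tally; a wildcard or empty
    formula on any participant also makes the tally inapplicable (skipped).
    A missing metabolite raises :class:`UnknownFormulaError`.
    """
    if reaction.rtype in BALANCE_EXEMPT_RTYPES:
        return ElementTally(applicable=False)

    tally: dict[str, float] = {}
    charges: list[float] = []
    all_charged = True
    for met_id, coef in reaction.stoichiometry.items():
        if met_id not in metabolites:
            raise UnknownFormulaError(
                f"reaction {reaction.id!r}: unknown metabolite {met_id!r}")
        met = metabolites[met_id]
        if met.formula == "":
            return ElementTally(applicable=False)
        counts = parse_formula(met.formula)
        if any(tok in counts for tok in WILDCARD_TOKENS):
            return ElementTally(applicable=False)
        for el, n in counts.items():
            tally[el] = tally.get(el, 0.0) + coef * n
        if met.charge is None:
            all_charged = False
        else:
            charges.append(coef * met.charge)
    charge = sum(charges) if all_charged else None
    return ElementTally(imbalance={el: v for el, v in tally.items() if v != 0},
                        charge_imbalance=charge)


def audit_model_balance(model: MetabolicModel) -> AuditReport:
    """Balance-check every non-exempt reaction of the model."""
    lookup = {m.id: m for m in model.metabolites}
    violations: list[tuple[str, ElementTally]] = []
    skipped: list[str] = []
    for rxn in model.reactions:
        if rxn.rtype in BALANCE_EXEMPT_RTYPES:
            continue
        tally = check_reaction_balance(rxn, lookup)
        if not tally.applicable:
            skipped.append(rxn.id)
        elif not tally.balanced:
            violations.append((rxn.id, tally))
    return AuditReport(violations=violations, skipped=skipped)


@dataclass
class BlockedExchangeResult:
    biomass_flux: float
    atp_yield: float | None
    passed: bool
    status: str


def blocked_exchange_audit(model: MetabolicModel,
                           atp_probe_id: str | None = None,
                           tol: float = GROWTH_TOL) -> BlockedExchangeResult:
    """Close every exchange in both directions and maximize biomass.

    A positive optimum means the network creates matter or energy from
    nothing (a futile / energy-generating loop).  If ``atp_probe_id`` names
    an ATP-hydrolysis reaction, its maximum is probed the same way.
    """
    closed = model.copy()
    for rxn in closed.reactions:
        if rxn.rtype == "exchange":
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    sol = solve_fba(closed)
    if not sol.optimal:
        return BlockedExchangeResult(0.0, None, passed=False, status=sol.status)
    biomass = sol.objective_value

    atp = None
    if atp_probe_id is not None:
        probe = closed.copy()
        probe.reaction(atp_probe_id)  # KeyError if absent
        probe.objective_id = atp_probe_id
        probe.reaction(atp_probe_id).rtype = "biomass"
        probe.objective.rtype = "biomass"
        atp_sol = solve_fba(probe)
        if not atp_sol.optimal:
            return BlockedExchangeResult(biomass, None, passed=False,
                                         status=atp_sol.status)
        atp = atp_sol.objective_value

    passed = biomass <= tol and (atp is None or atp <= tol)
    return BlockedExchangeResult(biomass, atp, passed=passed, status="optimal")


@dataclass
class NutrientRequirementResult:
    table: pd.DataFrame  # columns: condition, biomass_flux
    satisfied: bool

    def flux(self, condition: str) -> float:
        row = self.table[self.table.condition == condition]
        return float(row.biomass_flux.iloc[0])


def nutrient_requirement_audit(model: MetabolicModel, media: Media,
                               carbon_sources: list[str],
                               nitrogen_sources: list[str],
                               tol: float = GROWTH_TOL) -> NutrientRequirementResult:
    """Growth under full media vs. media deprived of all C or all N sources.

    The requirement is satisfied when both deprived conditions give no
    growth while the full media does.
    """
    def deprived(drop: list[str], label: str) -> Media:
        return Media({k: v for k, v in media.uptakes.items() if k not in drop},
                     name=f"{media.name}-{label}")

    conditions = [
        ("full", media),
        ("no_carbon", deprived(carbon_sources, "C")),
        ("no_nitrogen", deprived(nitrogen_sources, "N")),
    ]
    rows = []
    for label, m in conditions:
        sol = solve_fba(model, m)
        rows.append({"condition": label,
                     "biomass_flux": sol.objective_value if sol.optimal else 0.0})
    table = pd.DataFrame(rows)
    flux = {r["condition"]: r["biomass_flux"] for r in rows}
    satisfied = (flux["full"] > tol and flux["no_carbon"] <= tol
                 and flux["no_nitrogen"] <= tol)
    return NutrientRequirementResult(table=table, satisfied=satisfied)


def directionality_report(model: MetabolicModel, media: Media,
                          objective_fraction: float = 1.0) -> list[str]:
    """Reversible reactions whose reverse direction is unusable at optimum.

    Report-only (candidates for tightening to irreversible); no bounds are
    changed.
    """
    constrained = apply_media(model, media)
    reversible = [r.id for r in constrained.reactions if r.reversible]
    if not reversible:
        return []
    fva = run_fva(constrained, reaction_ids=reversible,
                  objective_fraction=objective_fraction)
    return [rid for rid in reversible if fva[rid][0] >= -FEASIBILITY_TOL * 10]
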