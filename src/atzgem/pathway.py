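"""The hydrolytic atrazine degradation pathway of P. aurescens TC1.

Atrazine (C8H14ClN5) is dechlorinated by triazine hydrolase (TrzN) to
hydroxyatrazine, then two hydrolytic deaminations (AtzB, AtzC) strip the
side chains, releasing ethylamine and isopropylamine and leaving cyanuric
acid.  TC1 does not cleave the triazine ring: cyanuric acid is exported and
accumulates stoichiometrically, one mole per mole of atrazine degraded,
while the alkylamines are catabolized — ethylamine to acetaldehyde plus
ammonium, isopropylamine (via a lumped multi-step route) to L-alanine.  Of
atrazine's 8 C and 5 N, the 5 C and 2 N of the side chains are therefore
bioavailable; 3 C and 3 N leave in the ring.

Every reaction is written fully elementally and charge balanced, with
explicit H2O/H+/NH4+ and chloride released as Cl- + H+.  The true amine
oxidation steps are O2/cofactor dependent; the lumped reactions here are
deliberately cofactor-neutral, releasing the reducing equivalents as
secreted H2 so the bookkeeping closes without committing to a specific
electron acceptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import CYTOSOL, EXTRACELLULAR, MetabolicModel, Metabolite, Reaction
from .curation import check_reaction_balance
from .formulas import parse_formula

__all__ = ["PathwaySpec", "build_atrazine_pathway", "inject_pathway",
           "bioavailable_cn", "PathwayInjectionError"]


class PathwayInjectionError(ValueError):
    pass


@dataclass
class PathwaySpec:
    """A balanced, injectable reaction set.

    ``entry_metabolite`` is the degraded compound (cytosolic id) whose atoms
    the bookkeeping traces; ``accumulating`` maps dead-end product ids to
    their molar yield per mole of entry compound.
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    entry_metabolite: str = ""
    accumulating: dict[str, float] = field(default_factory=dict)
    name: str = "pathway"

    def metabolite(self, met_id: str) -> Metabolite:
        return next(m for m in self.metabolites if m.id == met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        return next(r for r in self.reactions if r.id == rxn_id)

    def validate_balance(self) -> None:
        """Raise if any non-exempt reaction is elementally unbalanced."""
        lookup = {m.id: m for m in self.metabolites}
        for rxn in self.reactions:
            tally = check_reaction_balance(rxn, lookup)
            if not tally.balanced:
                raise PathwayInjectionError(
                    f"pathway reaction {rxn.id!r} unbalanced: {tally.imbalance}, "
                    f"charge {tally.charge_imbalance}")


def _met(mid, name, formula, charge, compartment=CYTOSOL):
    return Metabolite(id=mid, name=name, formula=formula, charge=charge,
                      compartment=compartment)


def build_atrazine_pathway() -> PathwaySpec:
    """TrzN/AtzB/AtzC plus lumped alkylamine catabolism, fully balanced.

    Reactions
    ---------
    TrzN : atz_c + h2o_c -> hxatz_c + cl_c + h_c
    AtzB : hxatz_c + h2o_c -> ipamd_c + etham_c
    AtzC : ipamd_c + h2o_c -> cya_c + ipa_c
    ETHAM_DEAM : etham_c + h2o_c + h_c -> acald_c + nh4_c + h2_c
    IPA_ALA : ipa_c + 2 h2o_c -> ala__L_c + 3 h2_c   (lumped multi-step)
    plus atrazine uptake and cyanuric-acid export (transport + exchange).
    """
    metabolites = [
        _met("atz_c", "atrazine", "C8H14ClN5", 0),
        _met("atz_e", "atrazine", "C8H14ClN5", 0, EXTRACELLULAR),
        _met("hxatz_c", "hydroxyatrazine", "C8H15N5O", 0),
        _met("ipamd_c", "N-isopropylammelide", "C6H10N4O2", 0),
        _met("cya_c", "cyanuric acid", "C3H3N3O3", 0),
        _met("cya_e", "cyanuric acid", "C3H3N3O3", 0, EXTRACELLULAR),
        _met("etham_c", "ethylamine", "C2H7N", 0),
        _met("ipa_c", "isopropylamine", "C3H9N", 0),
        _met("acald_c", "acetaldehyde", "C2H4O", 0),
        _met("ala__L_c", "L-alanine", "C3H7NO2", 0),
        _met("nh4_c", "ammonium", "NH4", 1),
        _met("h2o_c", "water", "H2O", 0),
        _met("h_c", "proton", "H", 1),
        _met("h2_c", "hydrogen", "H2", 0),
        _met("cl_c", "chloride", "Cl", -1),
    ]
    rxn = Reaction
    reactions = [
        rxn("TrzN", {"atz_c": -1, "h2o_c": -1, "hxatz_c": 1, "cl_c": 1, "h_c": 1},
            0, 1000, name="triazine hydrolase"),
        rxn("AtzB", {"hxatz_c": -1, "h2o_c": -1, "ipamd_c": 1, "etham_c": 1},
            0, 1000, name="hydroxyatrazine hydrolase"),
        rxn("AtzC", {"ipamd_c": -1, "h2o_c": -1, "cya_c": 1, "ipa_c": 1},
            0, 1000, name="N-isopropylammelide isopropylamino hydrolase"),
        rxn("ETHAM_DEAM", {"etham_c": -1, "h2o_c": -1, "h_c": -1,
                           "acald_c": 1, "nh4_c": 1, "h2_c": 1},
            0, 1000, name="ethylamine deamination (lumped)"),
        rxn("IPA_ALA", {"ipa_c": -1, "h2o_c": -2, "ala__L_c": 1, "h2_c": 3},
            0, 1000, name="isopropylamine to L-alanine (lumped)"),
        rxn("ATZt", {"atz_e": -1, "atz_c": 1}, 0, 1000,
            name="atrazine uptake", rtype="transport"),
        rxn("CYAt", {"cya_c": -1, "cya_e": 1}, 0, 1000,
            name="cyanuric acid export", rtype="transport"),
        rxn("EX_atz", {"atz_e": -1}, 0, 1000, name="atrazine exchange",
            rtype="exchange"),
        rxn("EX_cya", {"cya_e": -1}, 0, 1000, name="cyanuric acid exchange",
            rtype="exchange"),
    ]
    spec = PathwaySpec(metabolites=metabolites, reactions=reactions,
                       entry_metabolite="atz_c",
                       accumulating={"cya_c": 1.0},
                       name="atrazine degradation (TrzN/AtzB/AtzC)")
    spec.validate_balance()
    return spec


def inject_pathway(model: MetabolicModel, spec: PathwaySpec, *,
                   overwrite: bool = False) -> MetabolicModel:
    """Return ``model`` extended with the pathway's reactions and species.

    Metabolites already present in the model are reused, provided their
    formula agrees with the pathway's (a mismatch raises — the pathway's
    balance proof would no longer transfer).  A reaction-id collision raises
    unless ``overwrite``.
    """
    out = model.copy()
    collisions = [r.id for r in spec.reactions if out.has_reaction(r.id)]
    if collisions and not overwrite:
        raise PathwayInjectionError(
            f"pathway reaction ids already present: {collisions} "
            f"(pass overwrite=True to replace)")
    if collisions:
        out.reactions = [r for r in out.reactions if r.id not in set(collisions)]

    for met in spec.metabolites:
        if out.has_metabolite(met.id):
            existing = out.metabolite(met.id)
            if existing.formula and met.formula and \
                    parse_formula(existing.formula) != parse_formula(met.formula):
                raise PathwayInjectionError(
                    f"metabolite {met.id!r} exists with formula "
                    f"{existing.formula!r}, pathway expects {met.formula!r}")
        else:
            out.metabolites.append(_copy_met(met))
    out.reactions.extend(r.copy() for r in spec.reactions)
    out._reindex()
    out.validate()
    return out


def _copy_met(met: Metabolite) -> Metabolite:
    return Metabolite(id=met.id, name=met.name, formula=met.formula,
                      charge=met.charge, compartment=met.compartment,
                      boundary=met.boundary)


def bioavailable_cn(spec: PathwaySpec) -> tuple[float, float]:
    """Carbon and nitrogen atoms per mole of entry compound that reach
    catabolizable products (i.e. everything not in an accumulating dead end).

    For the canonical atrazine pathway: (8 - 3, 5 - 3) = (5, 2).
    """
    if not spec.entry_metabolite:
        return (0.0, 0.0)
    entry = parse_formula(spec.metabolite(spec.entry_metabolite).formula)
    c = float(entry.get("C", 0))
    n = float(entry.get("N", 0))
    for met_id, yield_per_mole in spec.accumulating.items():
        counts = parse_formula(spec.metabolite(met_id).formula)
        c -= yield_per_mole * counts.get("C", 0)
        n -= yield_per_mole * counts.get("N", 0)
    return (c, n)
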