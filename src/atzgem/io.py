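"""Model I/O: SBML (Level 3 + FBC, with a legacy fallback) and TSV tables.

The SBML reader targets Level 3 with the flux-bounds/objective (``fbc``)
extension.  Files from older ModelSEED-style pipelines that store bounds as
kinetic-law parameters named ``LOWER_BOUND``/``UPPER_BOUND`` are read through
a documented fallback.  The objective must be recoverable from the FBC
objective list (or passed explicitly); there is no silent default.

Table I/O uses two delimited files:

``metabolites``: columns ``id``, ``compartment`` (``c``/``e``); optional
``name``, ``formula``, ``charge``, ``boundary``.

``reactions``: columns ``id``, ``equation``, ``lower_bound``,
``upper_bound``; optional ``name``, ``gpr``, ``rtype``, ``objective``
(truthy marks the biomass objective).  Equations use ``2 a_c + b_c -->
c_c``; an empty product side writes an exchange drain.
"""

from __future__ import annotations

import math
import re

import libsbml
import pandas as pd

from .core import (
    CYTOSOL,
    EXTRACELLULAR,
    Media,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
)

__all__ = [
    "SBMLParseError",
    "SchemaError",
    "read_sbml",
    "write_sbml",
    "read_model_tables",
    "write_model_tables",
    "read_media_table",
    "write_media_table",
    "reaction_equation",
    "parse_reaction_equation",
]


class SBMLParseError(ValueError):
    """The file is not readable SBML; message lists line-numbered errors."""


class SchemaError(ValueError):
    """A delimited table is missing a required column or id."""


_EXTRACELLULAR_IDS = {"e", "e0", "extracellular", "extraorganism", "extra_organism"}


def _map_compartment(compartment_id: str) -> str:
    return EXTRACELLULAR if compartment_id.lower() in _EXTRACELLULAR_IDS else CYTOSOL


def infer_reaction_type(stoichiometry: dict[str, float],
                        compartment_of: dict[str, str],
                        is_objective: bool) -> str:
    """Classify a reaction as exchange / transport / cytosolic / biomass.

    Exchange: a single-metabolite extracellular drain.  Transport: spans both
    compartments.  The declared objective is the biomass reaction.
    """
    if is_objective:
        return "biomass"
    compartments = {compartment_of[m] for m in stoichiometry}
    if len(stoichiometry) == 1 and compartments == {EXTRACELLULAR}:
        return "exchange"
    if len(compartments) > 1:
        return "transport"
    return "cytosolic"


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def _sbml_errors(document: libsbml.SBMLDocument) -> list[str]:
    out = []
    for i in range(document.getNumErrors()):
        err = document.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            out.append(f"line {err.getLine()}: {err.getMessage().strip()}")
    return out


def _legacy_bounds(reaction: libsbml.Reaction) -> tuple[float | None, float | None]:
    lb = ub = None
    kl = reaction.getKineticLaw()
    if kl is not None:
        for i in range(kl.getNumParameters()):
            p = kl.getParameter(i)
            if p.getId() == "LOWER_BOUND":
                lb = p.getValue()
            elif p.getId() == "UPPER_BOUND":
                ub = p.getValue()
    return lb, ub


_NOTE_FIELD = re.compile(r"(?:GENE_ASSOCIATION|FORMULA|CHARGE)\s*:\s*([^<\n]*)")


def _note_field(sbase: libsbml.SBase, key: str) -> str | None:
    if not sbase.isSetNotes():
        return None
    notes = sbase.getNotesString()
    m = re.search(rf"{key}\s*:\s*([^<\n]*)", notes)
    return m.group(1).strip() if m else None


def read_sbml(path: str, objective_id: str | None = None) -> MetabolicModel:
    """Read an SBML file into a :class:`MetabolicModel`.

    Parameters
    ----------
    path:
        SBML file (L3+FBC preferred; legacy kinetic-law bounds accepted).
    objective_id:
        Overrides / supplies the biomass objective when the file carries no
        FBC objective.

    Raises
    ------
    SBMLParseError
        On malformed XML (message lists offending lines) or when no objective
        can be recovered.
    """
    document = libsbml.readSBMLFromFile(path)
    errors = _sbml_errors(document)
    if errors:
        raise SBMLParseError(f"{path}: " + "; ".join(errors))
    sbml_model = document.getModel()
    if sbml_model is None:
        raise SBMLParseError(f"{path}: file contains no model")

    mplug = sbml_model.getPlugin("fbc")

    metabolites: list[Metabolite] = []
    compartment_of: dict[str, str] = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = ""
        charge: int | None = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        if not formula:
            formula = _note_field(sp, "FORMULA") or ""
        if charge is None:
            note_charge = _note_field(sp, "CHARGE")
            if note_charge:
                try:
                    charge = int(float(note_charge))
                except ValueError:
                    charge = None
        compartment = _map_compartment(sp.getCompartment())
        compartment_of[sp.getId()] = compartment
        metabolites.append(Metabolite(
            id=sp.getId(),
            name=sp.getName() or "",
            formula=formula,
            charge=charge,
            compartment=compartment,
            boundary=bool(sp.getBoundaryCondition()),
        ))

    if objective_id is None and mplug is not None:
        active = mplug.getActiveObjective()
        if active is None and mplug.getNumObjectives() > 0:
            active = mplug.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            objective_id = active.getFluxObjective(0).getReaction()
    if objective_id is None:
        raise SBMLParseError(
            f"{path}: no objective declared (FBC objective list empty); "
            f"pass objective_id explicitly"
        )

    reactions: list[Reaction] = []
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}

        rplug = rxn.getPlugin("fbc")
        lb = ub = None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                p = sbml_model.getParameter(rplug.getLowerFluxBound())
                lb = p.getValue() if p is not None else None
            if rplug.isSetUpperFluxBound():
                p = sbml_model.getParameter(rplug.getUpperFluxBound())
                ub = p.getValue() if p is not None else None
        if lb is None or ub is None:
            legacy_lb, legacy_ub = _legacy_bounds(rxn)
            lb = lb if lb is not None else legacy_lb
            ub = ub if ub is not None else legacy_ub
        if lb is None or ub is None:
            # spec default convention where the file is silent
            reversible = rxn.getReversible()
            lb = -1000.0 if reversible and lb is None else (lb or 0.0)
            ub = 1000.0 if ub is None else ub

        gpr = ""
        if rplug is not None:
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None and gpa.getAssociation() is not None:
                gpr = gpa.getAssociation().toInfix()
        if not gpr:
            gpr = _note_field(rxn, "GENE_ASSOCIATION") or ""

        rtype = infer_reaction_type(stoich, compartment_of, rxn.getId() == objective_id)
        reactions.append(Reaction(
            id=rxn.getId(),
            name=rxn.getName() or "",
            stoichiometry=stoich,
            lower_bound=float(lb),
            upper_bound=float(ub),
            gpr=gpr,
            rtype=rtype,
        ))

    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_id=objective_id,
        id=sbml_model.getId() or "model",
        name=sbml_model.getName() or "",
    )
    model.validate()
    return model


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Serialize ``model`` as SBML Level 3 Version 1 with FBC v2."""
    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    document = libsbml.SBMLDocument(ns)
    document.setPackageRequired("fbc", False)
    sm = document.createModel()
    sm.setId(model.id)
    if model.name:
        sm.setName(model.name)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(False)

    for comp_id in (CYTOSOL, EXTRACELLULAR):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(met.id)
        if met.name:
            sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setBoundaryCondition(met.boundary)
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setInitialAmount(0.0)
        splug = sp.getPlugin("fbc")
        if met.formula:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(int(met.charge))

    def _bound_parameter(value: float, pid: str) -> str:
        p = sm.createParameter()
        p.setId(pid)
        p.setValue(value)
        p.setConstant(True)
        return pid

    for rxn in model.reactions:
        sr = sm.createReaction()
        sr.setId(rxn.id)
        if rxn.name:
            sr.setName(rxn.name)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_parameter(rxn.lower_bound, f"{rxn.id}_lb"))
        rplug.setUpperFluxBound(_bound_parameter(rxn.upper_bound, f"{rxn.id}_ub"))
        if rxn.gpr:
            gpa = rplug.createGeneProductAssociation()
            gpa.setAssociation(rxn.gpr, True, True)

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    flux_obj = objective.createFluxObjective()
    flux_obj.setReaction(model.objective_id)
    flux_obj.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(document, path) != 1:
        raise IOError(f"cannot write SBML to {path}")


# ---------------------------------------------------------------------------
# reaction equation strings
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "<->", "-->", "->")


def reaction_equation(rxn: Reaction) -> str:
    """Human-readable equation, e.g. ``atz_c + h2o_c --> hxatz_c + cl_c``."""
    def side(items):
        terms = []
        for met_id, coef in items:
            coef = abs(coef)
            terms.append(met_id if coef == 1 else f"{coef:g} {met_id}")
        return " + ".join(terms)

    subs = sorted((m, c) for m, c in rxn.stoichiometry.items() if c < 0)
    prods = sorted((m, c) for m, c in rxn.stoichiometry.items() if c > 0)
    return f"{side(subs)} --> {side(prods)}".strip()


def parse_reaction_equation(equation: str) -> dict[str, float]:
    """Parse an equation string back into a signed stoichiometry map."""
    for arrow in _ARROWS:
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            break
    else:
        raise SchemaError(f"equation {equation!r} has no reaction arrow")

    def side(text: str, sign: float, out: dict[str, float]):
        text = text.strip()
        if not text:
            return
        for term in text.split(" + "):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 2:
                coef, met_id = float(parts[0]), parts[1]
            elif len(parts) == 1:
                coef, met_id = 1.0, parts[0]
            else:
                raise SchemaError(f"cannot parse equation term {term!r}")
            out[met_id] = out.get(met_id, 0.0) + sign * coef

    stoich: dict[str, float] = {}
    side(left, -1.0, stoich)
    side(right, +1.0, stoich)
    return {k: v for k, v in stoich.items() if v != 0.0}


# ---------------------------------------------------------------------------
# delimited tables
# ---------------------------------------------------------------------------

def _require_columns(frame: pd.DataFrame, required: list[str], what: str):
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"{what} table is missing required column {col!r}")


def read_model_tables(metabolites_path: str, reactions_path: str,
                      sep: str = "\t", model_id: str = "model") -> MetabolicModel:
    """Build a model from metabolite and reaction tables (see module docs)."""
    mets = pd.read_csv(metabolites_path, sep=sep).fillna("")
    rxns = pd.read_csv(reactions_path, sep=sep).fillna("")
    _require_columns(mets, ["id", "compartment"], "metabolites")
    _require_columns(rxns, ["id", "equation", "lower_bound", "upper_bound"], "reactions")

    metabolites = []
    for row in mets.itertuples(index=False):
        charge = getattr(row, "charge", "")
        metabolites.append(Metabolite(
            id=str(row.id),
            name=str(getattr(row, "name", "")),
            formula=str(getattr(row, "formula", "")),
            charge=int(charge) if charge != "" else None,
            compartment=str(row.compartment),
            boundary=bool(getattr(row, "boundary", False)),
        ))
    compartment_of = {m.id: m.compartment for m in metabolites}
    declared = set(compartment_of)

    objective_id = None
    reactions = []
    for row in rxns.itertuples(index=False):
        stoich = parse_reaction_equation(str(row.equation))
        unknown = sorted(set(stoich) - declared)
        if unknown:
            raise SchemaError(
                f"reaction {row.id!r} references unknown metabolite ids {unknown}"
            )
        is_objective = bool(getattr(row, "objective", False))
        if is_objective:
            objective_id = str(row.id)
        rtype = str(getattr(row, "rtype", "")) or infer_reaction_type(
            stoich, compartment_of, is_objective)
        reactions.append(Reaction(
            id=str(row.id),
            name=str(getattr(row, "name", "")),
            stoichiometry=stoich,
            lower_bound=float(row.lower_bound),
            upper_bound=float(row.upper_bound),
            gpr=str(getattr(row, "gpr", "")),
            rtype=rtype,
        ))
    if objective_id is None:
        raise SchemaError("reactions table declares no objective (column 'objective')")

    model = MetabolicModel(metabolites=metabolites, reactions=reactions,
                           objective_id=objective_id, id=model_id)
    model.validate()
    return model


def write_model_tables(model: MetabolicModel, metabolites_path: str,
                       reactions_path: str, sep: str = "\t") -> None:
    mets = pd.DataFrame([{
        "id": m.id, "name": m.name, "formula": m.formula,
        "charge": "" if m.charge is None else m.charge,
        "compartment": m.compartment, "boundary": m.boundary,
    } for m in model.metabolites])
    rxns = pd.DataFrame([{
        "id": r.id, "name": r.name, "equation": reaction_equation(r),
        "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
        "gpr": r.gpr, "rtype": r.rtype,
        "objective": r.id == model.objective_id,
    } for r in model.reactions])
    mets.to_csv(metabolites_path, sep=sep, index=False)
    rxns.to_csv(reactions_path, sep=sep, index=False)


def read_media_table(path: str, sep: str = "\t", name: str | None = None) -> Media:
    """Media table with columns ``exchange_id`` and ``max_uptake``."""
    frame = pd.read_csv(path, sep=sep)
    _require_columns(frame, ["exchange_id", "max_uptake"], "media")
    uptakes = {}
    for row in frame.itertuples(index=False):
        value = float(row.max_uptake)
        uptakes[str(row.exchange_id)] = math.inf if value == float("inf") else value
    return Media(uptakes=uptakes, name=name or str(path))


def write_media_table(media: Media, path: str, sep: str = "\t") -> None:
    frame = pd.DataFrame(
        sorted(media.uptakes.items()), columns=["exchange_id", "max_uptake"])
    frame.to_csv(path, sep=sep, index=False)
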