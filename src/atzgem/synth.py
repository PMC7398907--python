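"""Synthetic fixture models and media.

These generators make every pipeline stage testable at desk scale, with
closed-form optima standing in for a full genome-scale reconstruction:

``TOY-1``
    The minimal two-substrate network: glucose and ammonium exchanges and
    transporters feeding a biomass reaction ``1 glc_c + 0.5 nh4_c ->
    biomass``.  With uptake bounds (g, n) the FBA optimum is exactly
    ``mu* = min(g, 2 n)``.

``TOY-2``
    TOY-1 plus the downstream catabolism the atrazine pathway needs
    (acetaldehyde and L-alanine assimilation, water/proton/H2/chloride/
    phosphate infrastructure) and a small phosphate term in biomass.  After
    :func:`~atzgem.pathway.inject_pathway`, atrazine as sole C/N source at
    uptake ``a`` gives ``mu* = (5/6) a`` (5 bioavailable C per atrazine,
    6 C per glucose equivalent; nitrogen and phosphate non-limiting).

Random mass-balanced linear pathways (synthetic element ``E``) provide a
property-test corpus on which the balance and blocked-exchange audits hold
by construction.
"""

from __future__ import annotations

import math

import numpy as np

from .core import (
    CYTOSOL,
    EXTRACELLULAR,
    Media,
    MetabolicModel,
    Metabolite,
    Reaction,
)

__all__ = [
    "MMM_EXCHANGES",
    "WATER_PROTONS",
    "make_toy_model",
    "make_mmm_media",
    "make_random_balanced_model",
]

#: The 11 mineral-medium ion/gas exchanges (K+, Mn2+, CO2, Zn2+, SO4(2-),
#: Cu2+, Ca2+, HPO4(2-), Mg2+, Fe2+, Cl-).
MMM_EXCHANGES = (
    "EX_k", "EX_mn2", "EX_co2", "EX_zn2", "EX_so4", "EX_cu2",
    "EX_ca2", "EX_hpo4", "EX_mg2", "EX_fe2", "EX_cl",
)

#: Water and protons, freely available in every simulated medium (neither a
#: carbon nor a nitrogen source).
WATER_PROTONS = {"EX_h2o": 1000.0, "EX_h": 1000.0}


def _met(mid, name, formula, charge, compartment=CYTOSOL, boundary=False):
    return Metabolite(id=mid, name=name, formula=formula, charge=charge,
                      compartment=compartment, boundary=boundary)


def _pair(base, name, formula, charge):
    """Extracellular/cytosolic species pair plus transporter and exchange."""
    mets = [_met(f"{base}_e", name, formula, charge, EXTRACELLULAR),
            _met(f"{base}_c", name, formula, charge)]
    return mets


def _toy1() -> MetabolicModel:
    metabolites = [
        _met("glc_e", "D-glucose", "C6H12O6", 0, EXTRACELLULAR),
        _met("glc_c", "D-glucose", "C6H12O6", 0),
        _met("nh4_e", "ammonium", "NH4", 1, EXTRACELLULAR),
        _met("nh4_c", "ammonium", "NH4", 1),
        _met("biomass_c", "biomass", "", None, CYTOSOL, boundary=True),
    ]
    reactions = [
        Reaction("EX_glc", {"glc_e": -1}, -1000, 1000, name="glucose exchange",
                 rtype="exchange"),
        Reaction("EX_nh4", {"nh4_e": -1}, -1000, 1000, name="ammonium exchange",
                 rtype="exchange"),
        Reaction("T_glc", {"glc_e": -1, "glc_c": 1}, 0, 1000,
                 name="glucose transport", rtype="transport"),
        Reaction("T_nh4", {"nh4_e": -1, "nh4_c": 1}, 0, 1000,
                 name="ammonium transport", rtype="transport"),
        Reaction("BIOMASS", {"glc_c": -1, "nh4_c": -0.5, "biomass_c": 1},
                 0, 1000, name="biomass", rtype="biomass"),
    ]
    model = MetabolicModel(metabolites=metabolites, reactions=reactions,
                           objective_id="BIOMASS", id="TOY1", name="TOY-1")
    model.validate()
    return model


def _toy2() -> MetabolicModel:
    model = _toy1()
    model.id, model.name = "TOY2", "TOY-2"
    model.metabolites += [
        _met("acald_c", "acetaldehyde", "C2H4O", 0),
        _met("ala__L_c", "L-alanine", "C3H7NO2", 0),
        *_pair("h2o", "water", "H2O", 0),
        *_pair("h", "proton", "H", 1),
        *_pair("h2", "hydrogen", "H2", 0),
        *_pair("cl", "chloride", "Cl", -1),
        *_pair("hpo4", "hydrogenphosphate", "HPO4", -2),
    ]
    # biomass requires a pinch of phosphate on top of the TOY-1 stoichiometry
    model.reaction("BIOMASS").stoichiometry["hpo4_c"] = -0.1
    # ammonium is a byproduct of atrazine degradation: allow its secretion
    model.reaction("T_nh4").lower_bound = -1000.0
    model.reactions += [
        Reaction("ACALD_ASSIM", {"acald_c": -3, "h2o_c": -3, "glc_c": 1, "h2_c": 3},
                 0, 1000, name="acetaldehyde assimilation (lumped)"),
        Reaction("ALA_DEAM", {"ala__L_c": -1, "h_c": -1, "h2o_c": -1,
                              "nh4_c": 1, "glc_c": 0.5},
                 0, 1000, name="L-alanine deamination (lumped)"),
        Reaction("H2Ot", {"h2o_e": -1, "h2o_c": 1}, -1000, 1000,
                 name="water transport", rtype="transport"),
        Reaction("Ht", {"h_e": -1, "h_c": 1}, -1000, 1000,
                 name="proton transport", rtype="transport"),
        Reaction("H2t", {"h2_c": -1, "h2_e": 1}, 0, 1000,
                 name="hydrogen export", rtype="transport"),
        Reaction("CLt", {"cl_c": -1, "cl_e": 1}, 0, 1000,
                 name="chloride export", rtype="transport"),
        Reaction("HPO4t", {"hpo4_e": -1, "hpo4_c": 1}, 0, 1000,
                 name="phosphate transport", rtype="transport"),
        Reaction("EX_h2o", {"h2o_e": -1}, -1000, 1000, rtype="exchange"),
        Reaction("EX_h", {"h_e": -1}, -1000, 1000, rtype="exchange"),
        Reaction("EX_h2", {"h2_e": -1}, 0, 1000, rtype="exchange"),
        Reaction("EX_cl", {"cl_e": -1}, -1000, 1000, rtype="exchange"),
        Reaction("EX_hpo4", {"hpo4_e": -1}, -1000, 1000, rtype="exchange"),
    ]
    model._reindex()
    model.validate()
    return model


def make_toy_model(name: str) -> MetabolicModel:
    """Build a named fixture model (``TOY-1``, ``TOY-2`` or ``TOY-RANDOM``)."""
    key = name.upper().replace("_", "-")
    if key == "TOY-1":
        return _toy1()
    if key == "TOY-2":
        return _toy2()
    if key == "TOY-RANDOM":
        return make_random_balanced_model(seed=0, n_reactions=8)
    raise KeyError(f"unknown toy model {name!r} (expected TOY-1, TOY-2 or TOY-RANDOM)")


def make_mmm_media(supplements: dict[str, float] | None = None,
                   ion_bound: float = 1000.0) -> Media:
    """The 11-ion/gas minimal mineral medium, optionally supplemented.

    Supplements merge on top and take precedence over the ion defaults.
    Carbon and nitrogen sources are deliberately absent: on any model whose
    biomass requires C and N, growth on the bare MMM is zero.
    """
    uptakes = {ex: float(ion_bound) for ex in MMM_EXCHANGES}
    if supplements:
        uptakes.update(supplements)
    return Media(uptakes=uptakes, name="MMM" if not supplements else "MMM+")


def make_random_balanced_model(seed: int, n_reactions: int = 8) -> MetabolicModel:
    """Random linear pathway, elementally balanced and loop-free by design.

    Species carry formulas over a single synthetic element ``E`` (species i
    has formula ``E<m_i>``); each chain step's coefficients are chosen so
    that E atoms are conserved exactly, making the balance audit a
    construction guarantee rather than a numerical question.  Deterministic
    for a given seed.
    """
    if n_reactions < 3:
        raise ValueError("n_reactions must be >= 3 (exchange, transport, biomass)")
    rng = np.random.default_rng(seed)
    n_internal = n_reactions - 3
    n_species = n_internal + 1  # chain s0 .. s{n_internal}

    sizes = rng.integers(1, 7, size=n_species)
    metabolites = [
        _met("s0_e", "substrate", f"E{sizes[0]}", 0, EXTRACELLULAR),
    ]
    for i in range(n_species):
        metabolites.append(_met(f"s{i}_c", f"species {i}", f"E{sizes[i]}", 0))
    metabolites.append(_met("biomass_c", "biomass", "", None, CYTOSOL, boundary=True))

    reactions = [
        Reaction("EX_s0", {"s0_e": -1}, -1000, 1000, rtype="exchange"),
        Reaction("T_s0", {"s0_e": -1, "s0_c": 1}, 0, 1000, rtype="transport"),
    ]
    for i in range(n_internal):
        m_in, m_out = int(sizes[i]), int(sizes[i + 1])
        g = math.gcd(m_in, m_out)
        lb = -1000.0 if rng.random() < 0.3 else 0.0
        reactions.append(Reaction(
            f"R{i}", {f"s{i}_c": -(m_out // g), f"s{i + 1}_c": m_in // g},
            lb, 1000.0))
    last = f"s{n_species - 1}_c"
    reactions.append(Reaction("BIOMASS", {last: -1, "biomass_c": 1}, 0, 1000,
                              rtype="biomass"))
    model = MetabolicModel(metabolites=metabolites, reactions=reactions,
                           objective_id="BIOMASS", id=f"RAND{seed}",
                           name=f"random balanced model (seed {seed})")
    model.validate()
    return model
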