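"""Core data model for genome-scale metabolic networks.

A :class:`MetabolicModel` is a plain in-memory container: metabolites with
elemental formulas, reactions with stoichiometry and flux bounds
(mmol gDW^-1 h^-1), and a declared biomass objective.  Exchange reactions are
written as single-metabolite drains (``met_e ->``); uptake is the negative
flux direction and media therefore store uptake *magnitudes* that are applied
to exchange lower bounds.

Species marked ``boundary`` (SBML ``boundaryCondition``) are exempt from the
steady-state constraint; this is how the lumped biomass product is modelled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

__all__ = [
    "CYTOSOL",
    "EXTRACELLULAR",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "StoichiometricMatrix",
    "Media",
    "ModelValidationError",
    "build_stoichiometric_matrix",
    "apply_media",
    "model_summary",
    "parse_gene_ids",
]

CYTOSOL = "c"
EXTRACELLULAR = "e"
COMPARTMENTS = (CYTOSOL, EXTRACELLULAR)

REACTION_TYPES = ("exchange", "transport", "cytosolic", "biomass")


class ModelValidationError(ValueError):
    """A model or one of its components violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: str = ""
    charge: int | None = None
    compartment: str = CYTOSOL
    #: SBML boundaryCondition: excluded from the steady-state constraint.
    boundary: bool = False

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: compartment {self.compartment!r} "
                f"not in {COMPARTMENTS}"
            )


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    name: str = ""
    gpr: str = ""
    rtype: str = "cytosolic"

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.rtype not in REACTION_TYPES:
            raise ModelValidationError(
                f"reaction {self.id!r}: unknown type {self.rtype!r}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


_GPR_SPLIT = re.compile(r"\band\b|\bor\b|[()]", flags=re.IGNORECASE)


def parse_gene_ids(gpr: str) -> set[str]:
    """Distinct gene ids in a boolean gene-association expression.

    Only tokenisation is performed (``and``/``or``/parentheses are
    separators); the boolean structure is never evaluated.
    """
    return {tok.strip() for tok in _GPR_SPLIT.split(gpr) if tok.strip()}


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str
    id: str = "model"
    name: str = ""

    def __post_init__(self):
        self._met_index: dict[str, Metabolite] = {}
        self._rxn_index: dict[str, Reaction] = {}
        self._reindex()

    def _reindex(self):
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    # -- lookups -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def objective(self) -> Reaction:
        return self.reaction(self.objective_id)

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.rtype == "exchange"]

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= parse_gene_ids(r.gpr)
        return out

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            objective_id=self.objective_id,
            id=self.id,
            name=self.name,
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on any broken invariant."""
        if len(self._met_index) != len(self.metabolites):
            seen, dupes = set(), set()
            for m in self.metabolites:
                (dupes if m.id in seen else seen).add(m.id)
            raise ModelValidationError(f"duplicate metabolite ids: {sorted(dupes)}")
        if len(self._rxn_index) != len(self.reactions):
            seen, dupes = set(), set()
            for r in self.reactions:
                (dupes if r.id in seen else seen).add(r.id)
            raise ModelValidationError(f"duplicate reaction ids: {sorted(dupes)}")
        for r in self.reactions:
            if not r.stoichiometry:
                raise ModelValidationError(f"reaction {r.id!r}: empty stoichiometry")
            for met_id in r.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references undeclared metabolite {met_id!r}"
                    )
            if r.rtype == "exchange":
                ext = [m for m in r.stoichiometry if
                       self._met_index[m].compartment == EXTRACELLULAR]
                if len(r.stoichiometry) != 1 or len(ext) != 1:
                    raise ModelValidationError(
                        f"exchange reaction {r.id!r} must drain exactly one "
                        f"extracellular metabolite"
                    )
        if self.objective_id not in self._rxn_index:
            raise ModelValidationError(f"objective reaction {self.objective_id!r} not found")
        if self.objective.rtype != "biomass":
            raise ModelValidationError(
                f"objective reaction {self.objective_id!r} has type "
                f"{self.objective.rtype!r}, expected 'biomass'"
            )


@dataclass
class StoichiometricMatrix:
    """S (m x n): rows are metabolites, columns are reactions."""

    S: sparse.csr_matrix
    row_ids: list[str]
    col_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.S.shape

    def toarray(self) -> np.ndarray:
        return self.S.toarray()

    def row(self, met_id: str) -> int:
        return self.row_ids.index(met_id)

    def col(self, rxn_id: str) -> int:
        return self.col_ids.index(rxn_id)


def build_stoichiometric_matrix(model: MetabolicModel) -> StoichiometricMatrix:
    """Assemble S with S[i, j] = coefficient of metabolite i in reaction j."""
    row_ids = [m.id for m in model.metabolites]
    col_ids = [r.id for r in model.reactions]
    row_pos = {mid: i for i, mid in enumerate(row_ids)}
    S = sparse.lil_matrix((len(row_ids), len(col_ids)))
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            S[row_pos[met_id], j] = coef
    return StoichiometricMatrix(S=S.tocsr(), row_ids=row_ids, col_ids=col_ids)


@dataclass
class Media:
    """Map exchange-reaction id -> maximal uptake magnitude (>= 0)."""

    uptakes: dict[str, float] = field(default_factory=dict)
    name: str = "media"

    def __post_init__(self):
        for ex_id, value in self.uptakes.items():
            if value < 0:
                raise ModelValidationError(
                    f"media {self.name!r}: uptake for {ex_id!r} is negative ({value})"
                )

    def with_supplements(self, supplements: dict[str, float],
                         name: str | None = None) -> "Media":
        """New media with ``supplements`` merged on top (supplement wins)."""
        merged = dict(self.uptakes)
        merged.update(supplements)
        return Media(uptakes=merged, name=name or f"{self.name}+{len(supplements)}")

    def __contains__(self, ex_id: str) -> bool:
        return ex_id in self.uptakes

    def __len__(self) -> int:
        return len(self.uptakes)


def apply_media(model: MetabolicModel, media: Media, *,
                strict: bool = False) -> MetabolicModel:
    """Return a copy of ``model`` constrained to ``media``.

    Every exchange reaction not listed in the media has its uptake closed
    (lower bound 0); listed exchanges get lower bound ``-uptake``.  Secretion
    (upper bound) is left open.  The input model is not modified.

    Media ids that are not exchange reactions raise; ids absent from the
    model are ignored unless ``strict`` (media definitions such as the
    mineral medium are organism-independent and may list exchanges a small
    model lacks).
    """
    for ex_id in media.uptakes:
        if model.has_reaction(ex_id):
            if model.reaction(ex_id).rtype != "exchange":
                raise ModelValidationError(
                    f"media {media.name!r}: {ex_id!r} is not an exchange reaction"
                )
        elif strict:
            raise ModelValidationError(
                f"media {media.name!r}: exchange {ex_id!r} not present in model"
            )
    out = model.copy()
    for rxn in out.reactions:
        if rxn.rtype != "exchange":
            continue
        uptake = media.uptakes.get(rxn.id, 0.0)
        rxn.lower_bound = -float(uptake)
        # keep secretion open; a closed uptake must not leave ub < lb
        rxn.upper_bound = max(rxn.upper_bound, rxn.lower_bound)
    return out


def model_summary(model: MetabolicModel) -> dict[str, int]:
    """Network statistics: genes, reactions, exchange reactions, metabolites."""
    return {
        "genes": len(model.genes),
        "reactions": len(model.reactions),
        "exchange_reactions": sum(1 for r in model.reactions if r.rtype == "exchange"),
        "metabolites": len(model.metabolites),
    }
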