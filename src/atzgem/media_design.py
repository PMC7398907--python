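"""Media screening and design analyses.

* single-supplement growth screen over candidate exchange metabolites, with
  high / moderate / low classification relative to the screen maximum;
* two-source uptake gradient surfaces (e.g. carbon vs. nitrogen source);
* C:N ratio bookkeeping for supplements;
* the equimolar-nitrogen dose calculator used to design media in which each
  supplement delivers the same molar nitrogen as a reference compound
  (e.g. 30 mg/l atrazine).

Classification cutoffs are fractions of the screen maximum: ``low`` below
25 %, ``high`` at or above 66 %, ``moderate`` between.  The cutoffs are
scale-invariant (multiplying all growth rates by a constant preserves the
classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Media, MetabolicModel, ModelValidationError
from .fba import solve_fba
from .formulas import carbon_nitrogen_counts, molecular_weight, parse_formula

__all__ = [
    "ScreenResult",
    "GradientSurface",
    "Compound",
    "DoseResult",
    "supplement_screen",
    "classify_supplements",
    "gradient_scan",
    "cn_ratio",
    "equimolar_nitrogen_dose",
]

HIGH_FRACTION = 0.66
LOW_FRACTION = 0.25


@dataclass
class ScreenResult:
    """Per-candidate growth rates, sorted descending.

    ``table`` columns: exchange_id, growth_rate, carbon, nitrogen and (after
    :func:`classify_supplements`) a ``class`` column.
    """

    table: pd.DataFrame
    base_growth_rate: float
    supplement_bound: float

    @property
    def max_growth_rate(self) -> float:
        return float(self.table.growth_rate.max())

    def growth_rate(self, exchange_id: str) -> float:
        row = self.table[self.table.exchange_id == exchange_id]
        if row.empty:
            raise KeyError(f"candidate {exchange_id!r} not in screen")
        return float(row.growth_rate.iloc[0])

    def classification(self, exchange_id: str) -> str:
        row = self.table[self.table.exchange_id == exchange_id]
        if row.empty or "class" not in self.table.columns:
            raise KeyError(f"no classification for {exchange_id!r}")
        return str(row["class"].iloc[0])


def supplement_screen(model: MetabolicModel, base_media: Media,
                      candidates: list[str],
                      supplement_bound: float = 10.0) -> ScreenResult:
    """Growth rate with each single candidate added to the base media.

    Every candidate must be an exchange reaction of the model.  The C and N
    atom counts of the exchanged metabolite are reported alongside (blank
    for wildcard/unknown formulas).  Adding a supplement relaxes the LP, so
    each growth rate is at least the base-media rate.
    """
    for cand in candidates:
        if not model.has_reaction(cand) or model.reaction(cand).rtype != "exchange":
            raise ModelValidationError(f"candidate {cand!r} is not an exchange reaction")
    base = solve_fba(model, base_media)
    base_mu = base.objective_value if base.optimal else 0.0

    rows = []
    for cand in candidates:
        media = base_media.with_supplements({cand: float(supplement_bound)})
        sol = solve_fba(model, media)
        mu = sol.objective_value if sol.optimal else 0.0
        met_id = next(iter(model.reaction(cand).stoichiometry))
        formula = model.metabolite(met_id).formula
        try:
            c, n = carbon_nitrogen_counts(formula)
        except Exception:
            c = n = None
        rows.append({"exchange_id": cand, "growth_rate": mu,
                     "carbon": c, "nitrogen": n})
    table = pd.DataFrame(rows).sort_values(
        "growth_rate", ascending=False, kind="stable").reset_index(drop=True)
    return ScreenResult(table=table, base_growth_rate=base_mu,
                        supplement_bound=float(supplement_bound))


def classify_supplements(result: ScreenResult,
                         high_fraction: float = HIGH_FRACTION,
                         low_fraction: float = LOW_FRACTION) -> ScreenResult:
    """Label each candidate high / moderate / low against the screen maximum."""
    if result.table.empty:
        raise ValueError("cannot classify an empty screen")
    top = result.max_growth_rate

    def label(mu: float) -> str:
        if top <= 0:
            return "low"
        frac = mu / top
        if frac >= high_fraction:
            return "high"
        if frac < low_fraction:
            return "low"
        return "moderate"

    table = result.table.copy()
    table["class"] = table.growth_rate.map(label)
    return ScreenResult(table=table, base_growth_rate=result.base_growth_rate,
                        supplement_bound=result.supplement_bound)


@dataclass
class GradientSurface:
    """Growth-rate surface over a two-exchange uptake grid.

    ``Z[i, j]`` is the optimum with ``source1`` bounded by ``grid1[i]`` and
    ``source2`` by ``grid2[j]``.  Because enlarging an uptake bound only
    relaxes the LP, Z is non-decreasing along both axes.
    """

    source1: str
    source2: str
    grid1: np.ndarray
    grid2: np.ndarray
    Z: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g1 in enumerate(self.grid1):
            for j, g2 in enumerate(self.grid2):
                rows.append({self.source1: g1, self.source2: g2,
                             "growth_rate": self.Z[i, j]})
        return pd.DataFrame(rows)


def gradient_scan(model: MetabolicModel, base_media: Media,
                  source1: str, source2: str,
                  grid1, grid2) -> GradientSurface:
    """Scan growth over a bound grid for two exchange reactions."""
    grid1 = np.asarray(grid1, dtype=float)
    grid2 = np.asarray(grid2, dtype=float)
    for grid, name in ((grid1, "grid1"), (grid2, "grid2")):
        if (grid < 0).any() or (np.diff(grid) < 0).any():
            raise ValueError(f"{name} must be non-negative and ascending")
    Z = np.zeros((len(grid1), len(grid2)))
    for i, g1 in enumerate(grid1):
        for j, g2 in enumerate(grid2):
            media = base_media.with_supplements({source1: g1, source2: g2})
            sol = solve_fba(model, media)
            Z[i, j] = sol.objective_value if sol.optimal else 0.0
    return GradientSurface(source1=source1, source2=source2,
                           grid1=grid1, grid2=grid2, Z=Z)


def cn_ratio(formula: str) -> tuple[int, int]:
    """(carbon, nitrogen) atom counts — the C:N ratio of a supplement."""
    return carbon_nitrogen_counts(formula)


@dataclass
class Compound:
    """A supplement compound; molecular weight defaults to the formula mass."""

    name: str
    formula: str
    mw: float | None = None
    conc_mg_per_l: float | None = None

    @property
    def molecular_weight(self) -> float:
        return self.mw if self.mw is not None else molecular_weight(self.formula)

    @property
    def n_atoms(self) -> int:
        return parse_formula(self.formula).get("N", 0)


@dataclass
class DoseResult:
    mg_per_l: float        #: unrounded dose
    rounded: float         #: dose at the requested rounding
    mmol_n_per_l: float    #: the shared molar-nitrogen level


def equimolar_nitrogen_dose(reference: Compound, target: Compound,
                            decimals: int = 0) -> DoseResult:
    """Concentration of ``target`` delivering the same molar N as ``reference``.

    dose = conc_ref / MW_ref * (N_ref / N_target) * MW_target

    With 30 mg/l atrazine (5 N, MW 215.7) as reference this reproduces the
    usual equimolar-nitrogen media design (~0.70 mmol N/l).
    """
    if reference.conc_mg_per_l is None:
        raise ValueError(f"reference {reference.name!r} has no concentration")
    if reference.n_atoms == 0:
        raise ValueError(f"reference {reference.name!r} contains no nitrogen")
    if target.n_atoms == 0:
        raise ValueError(
            f"cannot match nitrogen: target {target.name!r} contains no nitrogen")
    mmol_ref = reference.conc_mg_per_l / reference.molecular_weight
    mmol_n = mmol_ref * reference.n_atoms
    dose = mmol_n / target.n_atoms * target.molecular_weight
    return DoseResult(mg_per_l=dose, rounded=round(dose, decimals) if decimals
                      else float(round(dose)), mmol_n_per_l=mmol_n)
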