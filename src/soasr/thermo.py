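"""Reaction thermodynamics for sulfur-oxidation-coupled arsenate reduction.

The central reaction of interest is the chemolithotrophic coupling of
thiosulfate oxidation to arsenate reduction under standard alkaline
conditions:

    4 HAsO4^2- + S2O3^2- + 7 H2O -> 4 H3AsO3 + 2 SO4^2- + 6 OH-

This module represents chemical species with their standard free energies
of formation (ΔGf°, kJ/mol), computes the standard reaction free energy
ΔG° = Σ ν_i ΔGf°(products) − Σ ν_i ΔGf°(reactants), and audits reactions
for element balance, charge balance, electron transfer and product
stoichiometry.  No activity, ionic-strength or temperature corrections
are applied: everything here is at standard state, which is what the
formation-energy bookkeeping supports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "ChemicalSpecies",
    "ReactionSpec",
    "BalanceReport",
    "parse_formula",
    "gibbs_free_energy",
    "balance_report",
    "stoichiometric_ratio",
    "SOASR_SPECIES",
    "soasr_reaction",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an empirical formula like ``H3AsO3`` into an element→count map.

    Raises ``ValueError`` on anything that is not a sequence of element
    symbols with optional positive integer counts.
    """
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        n = int(m.group(2)) if m.group(2) else 1
        if n <= 0:
            raise ValueError(f"non-positive count in formula {formula!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + n
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class ChemicalSpecies:
    """A chemical species with formation energy and optional redox bookkeeping.

    Parameters
    ----------
    name
        Identifier, unique within a reaction (e.g. ``"HAsO4^2-"``).
    formula
        Element→count map; may be given as a formula string.
    charge
        Net charge in elementary units.
    dGf0
        Standard free energy of formation, kJ/mol.
    oxidation_states
        Optional element→oxidation-state map used for electron accounting.
    """

    name: str
    formula: Mapping[str, int]
    charge: int
    dGf0: float | None = None
    oxidation_states: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            object.__setattr__(self, "formula", parse_formula(self.formula))
        for elem, n in self.formula.items():
            if not (isinstance(n, int) and n > 0):
                raise ValueError(f"{self.name}: count for {elem} must be a positive integer")
        if self.dGf0 is not None and not _finite(self.dGf0):
            raise ValueError(f"{self.name}: dGf0 must be finite")


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


@dataclass(frozen=True)
class ReactionSpec:
    """A stoichiometric reaction: lists of (species, coefficient) per side."""

    reactants: Sequence[tuple[ChemicalSpecies, float]]
    products: Sequence[tuple[ChemicalSpecies, float]]

    def __post_init__(self) -> None:
        for side, label in ((self.reactants, "reactant"), (self.products, "product")):
            names = [sp.name for sp, _ in side]
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate {label} species names")
            for sp, coeff in side:
                if coeff <= 0:
                    raise ValueError(f"{label} {sp.name}: coefficient must be > 0")

    def product(self, name: str) -> tuple[ChemicalSpecies, float]:
        for sp, coeff in self.products:
            if sp.name == name:
                return sp, coeff
        raise KeyError(f"{name!r} is not a product of this reaction")

    def reversed(self) -> "ReactionSpec":
        return ReactionSpec(reactants=self.products, products=self.reactants)


@dataclass(frozen=True)
class BalanceReport:
    """Element/charge tallies and electron count for one reaction."""

    element_balance: dict[str, tuple[float, float]]
    charge_balance: tuple[float, float]
    electrons_transferred: float | None
    balanced: bool


def gibbs_free_energy(reaction: ReactionSpec) -> float:
    """Standard reaction free energy ΔG° in kJ/mol.

    ΔG° = Σ ν ΔGf°(products) − Σ ν ΔGf°(reactants).  Negative values mean
    the reaction is exergonic as written; the signed value is always
    returned, never an absolute value.

    Raises ``ValueError`` naming the first species that lacks a ΔGf°.
    """
    total = 0.0
    for side, sign in ((reaction.products, +1.0), (reaction.reactants, -1.0)):
        for sp, coeff in side:
            if sp.dGf0 is None:
                raise ValueError(f"species {sp.name!r} has no dGf0")
            total += sign * coeff * sp.dGf0
    return total


def balance_report(reaction: ReactionSpec) -> BalanceReport:
    """Tally elements and charge on each side; count electrons transferred.

    Electron transfer is derived from caller-supplied oxidation states:
    for every element assigned a state on each species that contains it,
    the coefficient-weighted oxidation-state total is compared across
    sides, and the electrons released by oxidised elements are summed.
    If any species containing a redox-relevant element lacks oxidation
    states the electron count is ``None`` rather than a guess.
    """
    elems: dict[str, list[float]] = {}
    charge = [0.0, 0.0]
    for idx, side in enumerate((reaction.reactants, reaction.products)):
        for sp, coeff in side:
            charge[idx] += coeff * sp.charge
            for elem, n in sp.formula.items():
                elems.setdefault(elem, [0.0, 0.0])[idx] += coeff * n

    element_balance = {e: (r, p) for e, (r, p) in sorted(elems.items())}
    balanced = all(abs(r - p) < 1e-9 for r, p in element_balance.values())
    balanced = balanced and abs(charge[0] - charge[1]) < 1e-9

    electrons = _electrons_transferred(reaction, elems)
    return BalanceReport(
        element_balance=element_balance,
        charge_balance=(charge[0], charge[1]),
        electrons_transferred=electrons,
        balanced=balanced,
    )


def _electrons_transferred(
    reaction: ReactionSpec, elems: Mapping[str, Sequence[float]]
) -> float | None:
    # Per element: ox-state totals per side; electrons released = positive
    # shift (oxidation) summed over elements.  Unassigned states on any
    # species carrying that element make the element unevaluable.
    any_states = any(
        sp.oxidation_states for side in (reaction.reactants, reaction.products) for sp, _ in side
    )
    if not any_states:
        return None
    released = 0.0
    for elem in elems:
        totals = [0.0, 0.0]
        for idx, side in enumerate((reaction.reactants, reaction.products)):
            for sp, coeff in side:
                if elem not in sp.formula:
                    continue
                if not sp.oxidation_states or elem not in sp.oxidation_states:
                    return None
                totals[idx] += coeff * sp.formula[elem] * sp.oxidation_states[elem]
        shift = totals[1] - totals[0]
        if shift > 0:
            released += shift
    return released


def stoichiometric_ratio(reaction: ReactionSpec, product_a: str, product_b: str) -> float:
    """Ratio of the stoichiometric coefficients of two products, a/b."""
    _, ca = reaction.product(product_a)
    _, cb = reaction.product(product_b)
    return ca / cb


# ---------------------------------------------------------------------------
# Shipped defaults: the six species of the thiosulfate/arsenate couple.
# Formation energies in kJ/mol; oxidation states follow the usual
# assignments (S in thiosulfate taken at its +2 average over both atoms).

SOASR_SPECIES: dict[str, ChemicalSpecies] = {
    sp.name: sp
    for sp in (
        ChemicalSpecies("HAsO4^2-", "HAsO4", -2, -714.0, {"H": 1, "As": 5, "O": -2}),
        ChemicalSpecies("S2O3^2-", "S2O3", -2, -647.0, {"S": 2, "O": -2}),
        ChemicalSpecies("H2O", "H2O", 0, -237.0, {"H": 1, "O": -2}),
        ChemicalSpecies("H3AsO3", "H3AsO3", 0, -640.0, {"H": 1, "As": 3, "O": -2}),
        ChemicalSpecies("SO4^2-", "SO4", -2, -745.0, {"S": 6, "O": -2}),
        ChemicalSpecies("OH-", "OH", -1, -157.0, {"H": 1, "O": -2}),
    )
}


def soasr_reaction(species: Mapping[str, ChemicalSpecies] | None = None) -> ReactionSpec:
    """The thiosulfate-driven arsenate reduction reaction, 4:1:7 → 4:2:6."""
    s = dict(SOASR_SPECIES if species is None else species)
    return ReactionSpec(
        reactants=[(s["HAsO4^2-"], 4.0), (s["S2O3^2-"], 1.0), (s["H2O"], 7.0)],
        products=[(s["H3AsO3"], 4.0), (s["SO4^2-"], 2.0), (s["OH-"], 6.0)],
    )
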