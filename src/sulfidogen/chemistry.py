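"""Chemical species, formula parsing and reaction balance checking.

This module is the substrate for everything else in the package: species are
element-count maps with a charge and a phase, reactions are signed lists of
(species, coefficient) terms normalised per mole of a reference substrate,
and balance checking verifies element and charge conservation to a fixed
numeric tolerance (stoichiometric coefficients are routinely fractional,
e.g. 0.25 SO4^2- or 1.75 H2S per glycerol).

The formula grammar covers what acid-mine-drainage media chemistry needs:
element symbols with (possibly fractional) counts, parenthesised groups,
hydrate suffixes ("FeSO4.7H2O", with ".", "*" or the typographic dot
accepted), and trailing ionic charges ("SO4^2-", "H+"). The electron is
representable as the pseudo-species ``e-`` (zero mass, charge -1) so that
half-reactions can be balanced like any other reaction.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "Species",
    "Reaction",
    "BalanceReport",
    "FormulaError",
    "parse_formula",
    "molar_mass",
    "mass_concentration_to_molarity",
    "check_balance",
    "ELECTRON",
    "atomic_weights",
]

#: tolerance for element/charge imbalance in coefficient arithmetic
BALANCE_TOL = 1e-9

PHASES = ("aqueous", "gas", "liquid", "solid")


class FormulaError(ValueError):
    """Raised for formulas that do not match the supported grammar."""


def atomic_weights() -> dict[str, float]:
    """Return the packaged table of standard atomic weights (g/mol).

    IUPAC conventional weights rounded to two decimals, shipped as static
    package data so molar masses are reproducible offline.
    """
    weights: dict[str, float] = {}
    text = resources.files("sulfidogen.data").joinpath("atomic_weights.csv").read_text()
    for row in csv.DictReader(text.splitlines()):
        weights[row["symbol"]] = float(row["weight"])
    return weights


_WEIGHTS = None


def _weights() -> dict[str, float]:
    global _WEIGHTS
    if _WEIGHTS is None:
        _WEIGHTS = atomic_weights()
    return _WEIGHTS


# --- formula grammar -------------------------------------------------------

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d+\.\d+|\d+)?|(\()|(\))(\d+\.\d+|\d+)?")
_CHARGE = re.compile(r"\^?(\d+)?([+-])$")
# hydrate separators the literature typesets inconsistently
_HYDRATE_SEPS = ("·", "⋅", "*", ".")


def _split_hydrate(text: str) -> tuple[str, float, str]:
    """Split ``FeSO4.7H2O`` into (anhydrous part, n, water formula)."""
    for sep in _HYDRATE_SEPS:
        if sep in text:
            head, _, tail = text.partition(sep)
            m = re.match(r"(\d+\.\d+|\d+)?(H2O)$", tail)
            if not m:
                raise FormulaError(f"malformed hydrate suffix {tail!r} in {text!r}")
            n = float(m.group(1)) if m.group(1) else 1.0
            return head, n, "H2O"
    return text, 0.0, ""


def _parse_plain(text: str) -> dict[str, float]:
    counts: dict[str, float] = {}
    stack: list[dict[str, float]] = [counts]
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise FormulaError(f"unexpected token at {text[pos:]!r} in {text!r}")
        if m.group(1):  # element
            sym = m.group(1)
            if sym not in _weights() and sym != "e":
                raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
            n = float(m.group(2)) if m.group(2) else 1.0
            stack[-1][sym] = stack[-1].get(sym, 0.0) + n
        elif m.group(3):  # "("
            stack.append({})
        elif m.group(4):  # ")"
            if len(stack) == 1:
                raise FormulaError(f"unbalanced ')' in {text!r}")
            mult = float(m.group(5)) if m.group(5) else 1.0
            group = stack.pop()
            for sym, n in group.items():
                stack[-1][sym] = stack[-1].get(sym, 0.0) + n * mult
        pos = m.end()
    if len(stack) != 1:
        raise FormulaError(f"unbalanced '(' in {text!r}")
    return counts


def parse_formula(text: str) -> tuple[dict[str, float], int]:
    """Parse a chemical formula into an element-count map and a charge.

    Supports hydrate dot notation and trailing charges, e.g.::

        parse_formula("FeSO4.7H2O") -> ({"Fe": 1, "S": 1, "O": 11, "H": 14}, 0)
        parse_formula("SO4^2-")     -> ({"S": 1, "O": 4}, -2)
    """
    text = text.strip()
    if not text:
        raise FormulaError("empty formula")
    # special-case names used for elemental sulfur and the electron
    if text in ("S(0)", "S0(s)"):
        return {"S": 1.0}, 0
    if text in ("e-", "e−"):
        return {}, -1

    charge = 0
    m = _CHARGE.search(text)
    if m:
        mag = int(m.group(1)) if m.group(1) else 1
        charge = mag if m.group(2) == "+" else -mag
        text = text[: m.start()]
        if not text:
            raise FormulaError("charge with no formula body")

    head, n_water, water = _split_hydrate(text)
    counts = _parse_plain(head)
    if n_water:
        for sym, n in _parse_plain(water).items():
            counts[sym] = counts.get(sym, 0.0) + n * n_water
    if not counts:
        raise FormulaError(f"no elements in {text!r}")
    return counts, charge


def molar_mass(counts: Mapping[str, float]) -> float:
    """Molar mass (g/mol) of an element-count map; electron counts as 0."""
    w = _weights()
    total = 0.0
    for sym, n in counts.items():
        if sym == "e":
            continue
        if sym not in w:
            raise FormulaError(f"no atomic weight for element {sym!r}")
        total += n * w[sym]
    return total


@dataclass(frozen=True)
class Species:
    """A chemical species: formula map, charge and phase."""

    name: str
    formula: Mapping[str, float] = field(default_factory=dict)
    charge: int = 0
    phase: str = "aqueous"

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        for sym, n in self.formula.items():
            if n <= 0:
                raise ValueError(f"non-positive count for {sym} in {self.name}")
        object.__setattr__(self, "formula", dict(self.formula))

    @classmethod
    def from_formula(cls, name: str, formula: str, phase: str = "aqueous") -> "Species":
        counts, charge = parse_formula(formula)
        return cls(name=name, formula=counts, charge=charge, phase=phase)

    @property
    def molar_mass(self) -> float:
        return molar_mass(self.formula)

    def render_formula(self) -> str:
        """Render the element-count map back to a plain formula string."""

        def fmt(n: float) -> str:
            if n == 1:
                return ""
            return f"{n:g}"

        body = "".join(f"{sym}{fmt(n)}" for sym, n in self.formula.items())
        if not body:  # the electron pseudo-species has no elements
            return "e-" if self.charge == -1 else ""
        if self.charge:
            sign = "+" if self.charge > 0 else "-"
            mag = abs(self.charge)
            body += f"^{mag}{sign}" if mag > 1 else f"^{sign}"
        return body

    def __hash__(self):
        return hash(self.name)


#: the electron pseudo-species for half-reactions
ELECTRON = Species(name="e-", formula={}, charge=-1, phase="aqueous")


def mass_concentration_to_molarity(mass_mg_per_l: float, species: Species) -> float:
    """Convert a mass concentration (mg/L) to molarity (mol/L).

    Used to turn media-recipe masses (e.g. 3000 mg/L FeSO4.7H2O) into the
    molar metal pools the titration and simulator start from.
    """
    if mass_mg_per_l < 0:
        raise ValueError("mass concentration must be non-negative")
    return mass_mg_per_l * 1e-3 / species.molar_mass


@dataclass
class Reaction:
    """A reaction as signed (species, coefficient) terms.

    Coefficients are negative for reactants and positive for products. The
    reference substrate is the species all "per mol substrate" reporting is
    normalised to; after :meth:`normalize` it carries coefficient -1.
    """

    id: str
    terms: list[tuple[Species, float]]
    reference_substrate: Species | None = None

    def __post_init__(self):
        if not any(c < 0 for _, c in self.terms) or not any(c > 0 for _, c in self.terms):
            raise ValueError(f"reaction {self.id}: need >=1 reactant and >=1 product")

    def coefficient(self, name: str) -> float:
        """Net signed coefficient of the species with this name (0 if absent)."""
        return sum(c for sp, c in self.terms if sp.name == name)

    def species(self) -> list[Species]:
        return [sp for sp, _ in self.terms]

    def normalize(self) -> "Reaction":
        """Scale so the reference substrate has coefficient exactly -1."""
        if self.reference_substrate is None:
            raise ValueError(f"reaction {self.id}: no reference substrate set")
        ref = self.coefficient(self.reference_substrate.name)
        if ref == 0:
            raise ValueError(
                f"reaction {self.id}: reference substrate "
                f"{self.reference_substrate.name} not present"
            )
        scale = -1.0 / ref
        return Reaction(
            id=self.id,
            terms=[(sp, c * scale) for sp, c in self.terms],
            reference_substrate=self.reference_substrate,
        )

    def scaled(self, k: float) -> "Reaction":
        return Reaction(
            id=self.id,
            terms=[(sp, c * k) for sp, c in self.terms],
            reference_substrate=self.reference_substrate,
        )

    def merged(self) -> "Reaction":
        """Combine duplicate species and drop terms with ~zero coefficient."""
        acc: dict[str, tuple[Species, float]] = {}
        for sp, c in self.terms:
            if sp.name in acc:
                acc[sp.name] = (sp, acc[sp.name][1] + c)
            else:
                acc[sp.name] = (sp, c)
        terms = [(sp, c) for sp, c in acc.values() if abs(c) > BALANCE_TOL]
        return Reaction(id=self.id, terms=terms, reference_substrate=self.reference_substrate)

    def __str__(self):
        lhs = " + ".join(
            f"{-c:g}{sp.name}" if c != -1 else sp.name for sp, c in self.terms if c < 0
        )
        rhs = " + ".join(
            f"{c:g}{sp.name}" if c != 1 else sp.name for sp, c in self.terms if c > 0
        )
        return f"{lhs} -> {rhs}"


@dataclass
class BalanceReport:
    """Per-element and charge imbalance of a reaction (products - reactants)."""

    element_imbalance: dict[str, float]
    charge_imbalance: float
    balanced: bool

    def worst(self) -> float:
        vals = [abs(v) for v in self.element_imbalance.values()]
        vals.append(abs(self.charge_imbalance))
        return max(vals) if vals else 0.0


def check_balance(rxn: Reaction, tol: float = BALANCE_TOL) -> BalanceReport:
    """Report element and charge conservation for a reaction.

    Never raises on imbalance: the report flags ``balanced`` iff every
    element imbalance and the charge imbalance are below ``tol``.
    """
    elements: dict[str, float] = {}
    charge = 0.0
    for sp, coeff in rxn.terms:
        for sym, n in sp.formula.items():
            elements[sym] = elements.get(sym, 0.0) + coeff * n
        charge += coeff * sp.charge
    balanced = abs(charge) <= tol and all(abs(v) <= tol for v in elements.values())
    return BalanceReport(element_imbalance=elements, charge_imbalance=charge, balanced=balanced)


def species_registry(extra: Iterable[Species] = ()) -> dict[str, Species]:
    """The packaged species set (everything the shipped reactions mention)."""
    from . import bioenergetics  # deferred: registry rides with the thermo table

    reg = {rec.species.name: rec.species for rec in bioenergetics.load_thermo_table().values()}
    for sp in extra:
        reg[sp.name] = sp
    return reg
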