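"""Electron-balance construction of coupled donor/acceptor reactions.

The catabolic reactions of sulfidogenic metabolism are assembled from half
reactions. Electrons released by an organic donor are counted from formal
mean carbon oxidation states (H = +1, O = -2, the carbon balance carries the
rest): glycerol (C at -2/3) releases 14 e- when fully oxidised to CO2 and
2 e- when incompletely oxidised to 1.5 acetate; sulfate accepts 8 e- per
mole on reduction to H2S and elemental sulfur accepts 2. Coupling scales the
acceptor by the electron ratio, cancels the electron pseudo-species, and
merges H2O/H+ so the overall reaction is element- and charge-balanced.

Yields per mole of substrate (sulfide, acetate, proton consumption =
alkalinity) are read directly off the balanced reaction. The incomplete
glycerol/S(0) pathway yields 4x the sulfide of the incomplete
glycerol/sulfate pathway (1.0 vs 0.25 mol/mol), the stoichiometric
expectation against which microcosm observations are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chemistry import ELECTRON, Reaction, Species, check_balance
from .bioenergetics import load_thermo_table

__all__ = [
    "HalfReaction",
    "YieldReport",
    "mean_carbon_oxidation_state",
    "electrons_transferred",
    "make_donor_half_reaction",
    "make_acceptor_half_reaction",
    "half_reaction_registry",
    "couple",
    "yields",
    "nutrient_requirement",
    "BIOMASS_FORMULA",
]

#: elemental composition used for N/P nutrient requirements of new biomass
BIOMASS_FORMULA = {"C": 5.0, "H": 7.0, "O": 2.0, "N": 1.0, "P": 0.1}

_OX_STATE = {"H": 1.0, "O": -2.0}


@dataclass
class HalfReaction:
    """A balanced half-reaction with the electron as an explicit term."""

    label: str
    reaction: Reaction
    electrons_per_substrate: float  # e- released (donor) or consumed (acceptor), > 0

    def __post_init__(self):
        if self.electrons_per_substrate <= 0:
            raise ValueError("electrons_per_substrate must be positive")
        report = check_balance(self.reaction)
        if not report.balanced:
            raise ValueError(
                f"half-reaction {self.label} unbalanced: worst {report.worst():.3g}"
            )


@dataclass
class YieldReport:
    """Per-mol-substrate yields read off a balanced coupled reaction.

    ``protons_consumed`` is positive when the reaction consumes H+
    (generates alkalinity) and negative when it produces acidity.
    """

    substrate: str
    acetate_yield: float
    sulfide_yield: float
    sulfate_consumed: float
    S0_consumed: float
    protons_consumed: float
    CO2_yield: float


def mean_carbon_oxidation_state(species: Species) -> float:
    """Formal mean oxidation state of carbon (H = +1, O = -2)."""
    counts = species.formula
    nC = counts.get("C", 0.0)
    if nC == 0:
        raise ValueError(f"{species.name} contains no carbon")
    others = sum(_OX_STATE[sym] * n for sym, n in counts.items() if sym in _OX_STATE)
    return (species.charge - others) / nC


def electrons_transferred(
    from_species: Species, to_species: Species, carbon_stoichiometry: float
) -> float:
    """Electrons released per mol substrate when ``from_species`` becomes
    ``carbon_stoichiometry`` mol of ``to_species``.

    Requires carbon conservation; a non-integer electron count (beyond
    tolerance) signals a wrong carbon stoichiometry and raises.
    """
    nC_sub = from_species.formula.get("C", 0.0)
    nC_prod = to_species.formula.get("C", 0.0) * carbon_stoichiometry
    if abs(nC_sub - nC_prod) > 1e-9:
        raise ValueError(
            f"carbon not conserved: {nC_sub} C in {from_species.name} vs "
            f"{nC_prod} C in {carbon_stoichiometry} x {to_species.name}"
        )
    ox_sub = mean_carbon_oxidation_state(from_species)
    ox_prod = mean_carbon_oxidation_state(to_species)
    electrons = nC_sub * (ox_prod - ox_sub)
    if abs(electrons - round(electrons)) > 1e-6:
        raise ValueError(
            f"non-integer electron count {electrons} for "
            f"{from_species.name} -> {to_species.name}"
        )
    return electrons


def _balance_half(
    label: str,
    substrate: Species,
    product: Species,
    carbon_stoichiometry: float,
    water: Species,
    proton: Species,
) -> tuple[Reaction, float]:
    """Balance substrate -> n product with H2O, H+ and e- (oxidation sense)."""
    terms: dict[str, tuple[Species, float]] = {
        substrate.name: (substrate, -1.0),
        product.name: (product, carbon_stoichiometry),
    }

    def _tot(sym: str) -> float:
        return sum(c * sp.formula.get(sym, 0.0) for sp, c in terms.values())

    nO = _tot("O")
    if abs(nO) > 1e-12:  # O balanced with water
        terms[water.name] = (water, terms.get(water.name, (water, 0.0))[1] - nO)
    nH = _tot("H")
    if abs(nH) > 1e-12:  # H balanced with protons
        terms[proton.name] = (proton, terms.get(proton.name, (proton, 0.0))[1] - nH)
    charge = sum(c * sp.charge for sp, c in terms.values())
    if abs(charge) > 1e-12:  # charge balanced with electrons
        terms[ELECTRON.name] = (ELECTRON, charge)
    rxn = Reaction(
        id=label, terms=list(terms.values()), reference_substrate=substrate
    ).merged()
    electrons = rxn.coefficient("e-")
    return rxn, electrons


def make_donor_half_reaction(
    label: str, substrate: Species, product: Species, carbon_stoichiometry: float
) -> HalfReaction:
    """Oxidation half-reaction releasing electrons (e- on the product side)."""
    rxn, e = _balance_half(
        label, substrate, product, carbon_stoichiometry, _water(), _proton()
    )
    if e <= 0:
        raise ValueError(f"{label}: not an oxidation (electrons {e})")
    return HalfReaction(label=label, reaction=rxn, electrons_per_substrate=e)


def make_acceptor_half_reaction(
    label: str, oxidant: Species, product: Species, product_stoichiometry: float = 1.0
) -> HalfReaction:
    """Reduction half-reaction consuming electrons (e- on the reactant side)."""
    rxn, e = _balance_half(
        label, oxidant, product, product_stoichiometry, _water(), _proton()
    )
    if e >= 0:
        raise ValueError(f"{label}: not a reduction (electrons {e})")
    return HalfReaction(label=label, reaction=rxn, electrons_per_substrate=-e)


def _thermo_species() -> dict[str, Species]:
    return {rec.species.name: rec.species for rec in load_thermo_table().values()}

def _water() -> Species:
    return _thermo_species()["water"]

def _proton() -> Species:
    return _thermo_species()["proton"]


def half_reaction_registry() -> dict[str, HalfReaction]:
    """The packaged donor/acceptor half-reactions of the study system."""
    sp = _thermo_species()
    return {
        "glycerol_to_CO2": make_donor_half_reaction(
            "glycerol_to_CO2", sp["glycerol"], sp["CO2"], 3.0
        ),
        "glycerol_to_acetate": make_donor_half_reaction(
            "glycerol_to_acetate", sp["glycerol"], sp["acetic_acid"], 1.5
        ),
        "acetate_to_CO2": make_donor_half_reaction(
            "acetate_to_CO2", sp["acetic_acid"], sp["CO2"], 2.0
        ),
        "sulfate_to_H2S": make_acceptor_half_reaction(
            "sulfate_to_H2S", sp["sulfate"], sp["H2S"]
        ),
        "S0_to_H2S": make_acceptor_half_reaction("S0_to_H2S", sp["S0"], sp["H2S"]),
    }


def couple(donor: HalfReaction, acceptor: HalfReaction, rxn_id: str | None = None) -> Reaction:
    """Couple a donor and an acceptor half-reaction by electron balance.

    The acceptor is scaled by donor_e/acceptor_e per mole of donor
    substrate; electrons cancel and H2O/H+ merge. The result is normalised
    per mole of donor substrate and verified to balance.
    """
    d = donor.reaction.normalize()
    scale = donor.electrons_per_substrate / acceptor.electrons_per_substrate
    a = acceptor.reaction.normalize().scaled(scale)
    combined = Reaction(
        id=rxn_id or f"{donor.label}+{acceptor.label}",
        terms=d.terms + a.terms,
        reference_substrate=d.reference_substrate,
    ).merged()
    if abs(combined.coefficient("e-")) > 1e-9:
        raise ValueError("electrons did not cancel in coupling")
    report = check_balance(combined)
    if not report.balanced:
        raise ValueError(
            f"coupled reaction unbalanced: {report.element_imbalance}, "
            f"charge {report.charge_imbalance}"
        )
    return combined.normalize()


def yields(rxn: Reaction) -> YieldReport:
    """Per-substrate yield report of a balanced, normalised reaction."""
    report = check_balance(rxn)
    if not report.balanced:
        raise ValueError(f"reaction {rxn.id} unbalanced")
    r = rxn.normalize()
    return YieldReport(
        substrate=r.reference_substrate.name,
        acetate_yield=max(r.coefficient("acetic_acid"), 0.0)
        + max(r.coefficient("acetate"), 0.0),
        sulfide_yield=max(r.coefficient("H2S"), 0.0),
        sulfate_consumed=max(-r.coefficient("sulfate"), 0.0),
        S0_consumed=max(-r.coefficient("S0"), 0.0),
        protons_consumed=-r.coefficient("proton"),
        CO2_yield=max(r.coefficient("CO2"), 0.0),
    )


def nutrient_requirement(
    biomass_C: float, formula: dict[str, float] | None = None
) -> tuple[float, float]:
    """N and P (mol) required to build ``biomass_C`` mol of biomass carbon.

    Default biomass composition C5H7O2N1P0.1 gives N = C/5 and P = C/50
    (molar N:P of 10).
    """
    if biomass_C < 0:
        raise ValueError("biomass carbon must be non-negative")
    formula = formula or BIOMASS_FORMULA
    per_C_N = formula.get("N", 0.0) / formula["C"]
    per_C_P = formula.get("P", 0.0) / formula["C"]
    return biomass_C * per_C_N, biomass_C * per_C_P
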