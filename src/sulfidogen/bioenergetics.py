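"""Standard-state and in-situ Gibbs free energies of catabolic reactions.

For a reaction with signed stoichiometric coefficients nu_i the standard
reaction energy is

    dGr0 = sum_i nu_i * dGf0_i

per mole of the reference substrate, and the in-situ (starting-condition)
energy is

    dGr' = dGr0(T) + R * T * ln Q,    Q = prod_i a_i ** nu_i

with R = 8.314e-3 kJ/mol/K. Activity conventions follow common practice for
dilute geomicrobial systems: aqueous molar concentrations are taken directly
as activities, {H+} = 10**-pH, gases enter as partial pressure in bar, and
solids and liquid water sit at unit activity. No ionic-strength correction
is applied.

Temperature adjustment of dGr0 away from 298.15 K uses Gibbs-Helmholtz with
a temperature-independent reaction enthalpy,

    dG(T) = dH - (T / Tref) * (dH - dG(Tref)),

when every species in the reaction has a formation enthalpy in the table;
otherwise dGr0 is carried over unchanged (the constant-dG0 fallback). Both
behaviours are explicit choices of ``temperature_adjust``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .chemistry import Reaction, Species, check_balance

__all__ = [
    "R_KJ",
    "T_REF",
    "ThermoRecord",
    "ThermoTable",
    "ConditionSet",
    "GibbsResult",
    "load_thermo_table",
    "load_reactions",
    "load_conditions",
    "delta_g_standard",
    "reaction_quotient",
    "temperature_adjust",
    "delta_g_insitu",
    "table2_analogue",
]

#: gas constant, kJ/mol/K
R_KJ = 8.314e-3
#: reference temperature of the formation-energy table, K
T_REF = 298.15


@dataclass(frozen=True)
class ThermoRecord:
    """Standard formation properties of one species at 298.15 K."""

    species: Species
    dGf0: float  # kJ/mol
    dHf0: float | None = None  # kJ/mol, optional
    source: str = ""


ThermoTable = dict[str, ThermoRecord]

_PHASE_BY_NAME = {}  # cache of the packaged table


def load_thermo_table(path: str | Path | None = None) -> ThermoTable:
    """Load a formation-energy table (packaged default or a CSV path)."""
    if path is None:
        text = resources.files("sulfidogen.data").joinpath("thermo.csv").read_text()
    else:
        text = Path(path).read_text()
    table: ThermoTable = {}
    for row in csv.DictReader(text.splitlines()):
        sp = Species.from_formula(row["name"], row["formula"], phase=row["phase"])
        dH = row.get("dHf0_kJ_mol", "")
        table[row["name"]] = ThermoRecord(
            species=sp,
            dGf0=float(row["dGf0_kJ_mol"]),
            dHf0=float(dH) if dH not in ("", None) else None,
            source=row.get("source", ""),
        )
    return table


def load_reactions(
    path: str | Path | None = None, table: ThermoTable | None = None
) -> dict[str, Reaction]:
    """Load the packaged (or a user) reaction set, normalised per substrate."""
    table = table or load_thermo_table()
    if path is None:
        text = resources.files("sulfidogen.data").joinpath("reactions.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)["reactions"]
    out: dict[str, Reaction] = {}
    for rid, spec in raw.items():
        terms = [(table[name].species, float(c)) for name, c in spec["terms"].items()]
        rxn = Reaction(
            id=rid, terms=terms, reference_substrate=table[spec["reference_substrate"]].species
        ).normalize()
        out[rid] = rxn
    return out


@dataclass
class ConditionSet:
    """Temperature plus the activity assignment defining Q.

    Every species in a reaction must resolve to exactly one of: an explicit
    aqueous activity, a gas partial pressure (bar), or the unit-activity set
    (solids, liquid water). H+ may be given via ``pH`` instead of an
    explicit activity.
    """

    temperature: float  # K
    activities: dict[str, float] = field(default_factory=dict)
    gas_pressures: dict[str, float] = field(default_factory=dict)
    fixed_unit_activity: set[str] = field(default_factory=set)
    pH: float | None = None

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        for name, a in {**self.activities, **self.gas_pressures}.items():
            if a <= 0:
                raise ValueError(f"non-positive activity for {name}")

    @classmethod
    def standard(cls, temperature: float = T_REF) -> "ConditionSet":
        """All-unit-activity conditions (Q = 1) at the given temperature."""
        return cls(temperature=temperature, fixed_unit_activity={"*"})

    def activity(self, name: str) -> float:
        if "*" in self.fixed_unit_activity:
            return 1.0
        if name in self.fixed_unit_activity:
            return 1.0
        if name in self.activities:
            return self.activities[name]
        if name in self.gas_pressures:
            return self.gas_pressures[name]
        if name == "proton" and self.pH is not None:
            return 10.0 ** (-self.pH)
        raise KeyError(f"no activity assignment for species {name!r}")


def load_conditions(path: str | Path | None = None) -> dict[str, ConditionSet]:
    """Load named condition sets (packaged default: the microcosm start)."""
    if path is None:
        text = resources.files("sulfidogen.data").joinpath("conditions.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)["conditions"]
    out = {}
    for name, c in raw.items():
        out[name] = ConditionSet(
            temperature=float(c["temperature_K"]),
            activities={k: float(v) for k, v in c.get("activities", {}).items()},
            gas_pressures={k: float(v) for k, v in c.get("gas_pressures", {}).items()},
            fixed_unit_activity=set(c.get("unit_activity", [])),
            pH=float(c["pH"]) if "pH" in c else None,
        )
    return out


@dataclass
class GibbsResult:
    """Energies of one reaction under one condition set, per mol substrate."""

    reaction_id: str
    normalization: str  # reference substrate label
    dG0_Tref: float  # kJ/mol substrate at 298.15 K
    dG0_T: float  # kJ/mol substrate at the condition temperature
    lnQ: float
    dG_insitu: float  # = dG0_T + R*T*lnQ
    temperature: float


def delta_g_standard(rxn: Reaction, table: ThermoTable, T_ref: float = T_REF) -> float:
    """Standard reaction energy (kJ/mol reference substrate) at ``T_ref``.

    ``T_ref`` must be the table's own reference temperature; the argument
    exists so callers state it explicitly.
    """
    if abs(T_ref - T_REF) > 1e-9:
        raise ValueError("the packaged table is defined at 298.15 K")
    by_name = {rec.species.name: rec for rec in table.values()}
    rxn = rxn.normalize() if rxn.reference_substrate is not None else rxn
    total = 0.0
    for sp, coeff in rxn.terms:
        if sp.name not in by_name:
            raise KeyError(f"no thermodynamic record for species {sp.name!r}")
        total += coeff * by_name[sp.name].dGf0
    return total


def reaction_quotient(rxn: Reaction, cond: ConditionSet) -> tuple[float, float]:
    """Return (Q, lnQ) for a normalised reaction under a condition set."""
    rxn = rxn.normalize() if rxn.reference_substrate is not None else rxn
    lnQ = 0.0
    for sp, coeff in rxn.terms:
        lnQ += coeff * math.log(cond.activity(sp.name))
    return math.exp(lnQ), lnQ


def temperature_adjust(
    dG0_ref: float, dH0: float | None, T_ref: float, T: float
) -> float:
    """Adjust a standard reaction energy from ``T_ref`` to ``T``.

    Gibbs-Helmholtz with T-independent dH when ``dH0`` is given; otherwise
    the constant-dG0 fallback (returns ``dG0_ref`` unchanged).
    """
    if T <= 0 or T_ref <= 0:
        raise ValueError("temperatures must be positive (kelvin)")
    if dH0 is None:
        return dG0_ref
    return dH0 - (T / T_ref) * (dH0 - dG0_ref)


def reaction_enthalpy(rxn: Reaction, table: ThermoTable) -> float | None:
    """Standard reaction enthalpy per mol substrate, or None if any species
    lacks a formation enthalpy."""
    by_name = {rec.species.name: rec for rec in table.values()}
    rxn = rxn.normalize() if rxn.reference_substrate is not None else rxn
    total = 0.0
    for sp, coeff in rxn.terms:
        rec = by_name.get(sp.name)
        if rec is None or rec.dHf0 is None:
            return None
        total += coeff * rec.dHf0
    return total


def delta_g_insitu(
    rxn: Reaction,
    table: ThermoTable,
    cond: ConditionSet,
    use_enthalpy: bool = True,
) -> GibbsResult:
    """Compose dGr0, temperature adjustment and RT lnQ into a GibbsResult."""
    rxn = rxn.normalize()
    report = check_balance(rxn)
    if not report.balanced:
        raise ValueError(f"reaction {rxn.id} is not balanced: worst {report.worst():.3g}")
    dG0 = delta_g_standard(rxn, table)
    dH0 = reaction_enthalpy(rxn, table) if use_enthalpy else None
    dG0_T = temperature_adjust(dG0, dH0, T_REF, cond.temperature)
    _, lnQ = reaction_quotient(rxn, cond)
    dG = dG0_T + R_KJ * cond.temperature * lnQ
    return GibbsResult(
        reaction_id=rxn.id,
        normalization=rxn.reference_substrate.name,
        dG0_Tref=dG0,
        dG0_T=dG0_T,
        lnQ=lnQ,
        dG_insitu=dG,
        temperature=cond.temperature,
    )


def table2_analogue(
    reactions: dict[str, Reaction] | None = None,
    table: ThermoTable | None = None,
    cond: ConditionSet | None = None,
):
    """Standard + in-situ energies for the packaged reaction set.

    Returns a pandas DataFrame with one row per reaction: the analogue of a
    published two-column reaction-energy table.
    """
    import pandas as pd

    table = table or load_thermo_table()
    reactions = reactions or load_reactions(table=table)
    cond = cond or load_conditions()["microcosm_start"]
    rows = []
    for rid, rxn in reactions.items():
        res = delta_g_insitu(rxn, table, cond)
        rows.append(
            {
                "reaction": rid,
                "equation": str(rxn),
                "dG0_298K_kJ_per_mol": res.dG0_Tref,
                f"dG_insitu_{cond.temperature:.0f}K_kJ_per_mol": res.dG_insitu,
                "lnQ": res.lnQ,
                "per_mol": res.normalization,
            }
        )
    return pd.DataFrame(rows)
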