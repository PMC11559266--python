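"""Acid/base speciation and Ksp-ranked metal-sulfide precipitation.

Two small pieces of solution chemistry sit between sulfide production and
the observable metal time courses:

* Henderson-Hasselbalch speciation of weak acids. For acetate (pKa 4.76)
  the neutral, membrane-permeable fraction 1/(1 + 10**(pH - pKa)) governs
  toxicity to acidophiles; at pH 5.5 it is 15.4%.

* A sequential, stoichiometric sulfide titration against the dissolved
  metal pool. Minerals are ranked by solubility product per mole of metal
  in the formula unit (so the 2:3 As2S3 compares sensibly with the 1:1
  monosulfides), and each mole of produced S(-II) precipitates the least
  soluble mineral first, conserving mass per metal and for sulfur. This is
  a threshold model, not a full equilibrium speciation: it captures the
  observed removal ordering (As before Zn before Fe) driven by log Ksp
  -71.8 (As2S3) < -24.7 (ZnS) < -17.3 (FeS) without modelling sulfide
  protonation or solid solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "AcidBasePair",
    "MetalSulfideMineral",
    "MetalPool",
    "ACETATE",
    "load_minerals",
    "protonated_fraction",
    "removal_order",
    "titrate_sulfide",
    "sulfide_metal_balance",
]


@dataclass(frozen=True)
class AcidBasePair:
    """A monoprotic weak acid/base pair with its pKa."""

    name: str
    pKa: float

    def __post_init__(self):
        if not (0 < self.pKa < 14):
            raise ValueError("pKa must lie in (0, 14)")


#: acetic acid / acetate at the experiment temperature
ACETATE = AcidBasePair(name="acetate", pKa=4.76)


@dataclass(frozen=True)
class MetalSulfideMineral:
    """A metal-sulfide solid and its dissolution solubility product."""

    name: str
    metal: str
    logKsp: float  # log10, dissolution convention
    metal_per_formula: int = 1
    sulfide_per_formula: int = 1

    def __post_init__(self):
        if self.logKsp >= 0:
            raise ValueError("packaged minerals must have logKsp < 0")
        if self.metal_per_formula < 1 or self.sulfide_per_formula < 1:
            raise ValueError("formula stoichiometries must be >= 1")

    @property
    def logKsp_per_metal(self) -> float:
        """Ranking key: log Ksp per mole of metal in the formula unit.

        Normalising by the metal stoichiometry makes minerals of unlike
        formula units (2:3 As2S3 vs 1:1 MeS) comparable on a per-metal-ion
        solubility basis and reproduces the observed removal sequence
        (As, then Zn, then Fe)."""
        return self.logKsp / self.metal_per_formula


@dataclass
class MetalPool:
    """Dissolved metal concentrations plus a per-mineral precipitate ledger.

    All concentrations in mol/L. ``dissolved + precipitated`` per metal is
    conserved by the titration.
    """

    dissolved: dict[str, float]
    precipitated: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for m, c in self.dissolved.items():
            if c < 0:
                raise ValueError(f"negative dissolved concentration for {m}")

    def copy(self) -> "MetalPool":
        return MetalPool(dict(self.dissolved), dict(self.precipitated))

    def total(self, metal: str, minerals: list[MetalSulfideMineral]) -> float:
        """Dissolved + precipitated (as metal mol/L) for one metal."""
        tot = self.dissolved.get(metal, 0.0)
        for mineral in minerals:
            if mineral.metal == metal:
                tot += self.precipitated.get(mineral.name, 0.0) * mineral.metal_per_formula
        return tot


def load_minerals(path: str | Path | None = None) -> list[MetalSulfideMineral]:
    """Load the packaged (or a user) mineral constant set."""
    if path is None:
        text = resources.files("sulfidogen.data").joinpath("minerals.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)["minerals"]
    return [
        MetalSulfideMineral(
            name=name,
            metal=m["metal"],
            logKsp=float(m["logKsp"]),
            metal_per_formula=int(m.get("metal_per_formula", 1)),
            sulfide_per_formula=int(m.get("sulfide_per_formula", 1)),
        )
        for name, m in raw.items()
    ]


def protonated_fraction(pH: float, pair: AcidBasePair) -> float:
    """Fraction of the acid in the neutral (protonated) form at this pH."""
    return 1.0 / (1.0 + 10.0 ** (pH - pair.pKa))


def removal_order(minerals: list[MetalSulfideMineral]) -> list[MetalSulfideMineral]:
    """Minerals sorted by ascending per-metal log Ksp (least soluble
    first); ties broken alphabetically by name."""
    if not minerals:
        raise ValueError("need at least one mineral")
    return sorted(minerals, key=lambda m: (m.logKsp_per_metal, m.name))


def titrate_sulfide(
    pool: MetalPool,
    total_sulfide: float,
    minerals: list[MetalSulfideMineral] | None = None,
) -> tuple[MetalPool, float]:
    """Allocate produced sulfide to metal precipitation in removal order.

    Returns the updated pool and the residual dissolved sulfide (mol/L).
    Each mineral consumes ``min(metal available, sulfide available *
    metal_per_formula / sulfide_per_formula)`` of its metal; mass is
    conserved per metal and for sulfur.
    """
    if total_sulfide < 0:
        raise ValueError("total_sulfide must be non-negative")
    minerals = minerals if minerals is not None else load_minerals()
    out = pool.copy()
    sulfide_left = total_sulfide
    for mineral in removal_order(minerals):
        if sulfide_left <= 0:
            break
        metal_avail = out.dissolved.get(mineral.metal, 0.0)
        if metal_avail <= 0:
            continue
        s_per_metal = mineral.sulfide_per_formula / mineral.metal_per_formula
        metal_removed = min(metal_avail, sulfide_left / s_per_metal)
        sulfide_used = metal_removed * s_per_metal
        out.dissolved[mineral.metal] = metal_avail - metal_removed
        out.precipitated[mineral.name] = (
            out.precipitated.get(mineral.name, 0.0)
            + metal_removed / mineral.metal_per_formula
        )
        sulfide_left -= sulfide_used
    return out, max(sulfide_left, 0.0)


def sulfide_metal_balance(delta_sulfide: float, delta_metals: float) -> float | None:
    """Ratio of S(-II) produced to divalent metal removed (mol/mol).

    Near 1 when removal is dominated by 1:1 MeS precipitation. Returns
    None (undefined) when no metal was removed.
    """
    if delta_metals == 0:
        return None
    if delta_metals < 0:
        raise ValueError("delta_metals must be positive")
    return delta_sulfide / delta_metals
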