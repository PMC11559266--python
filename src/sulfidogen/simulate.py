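"""Forward simulator for glycerol/sulfur amended microcosm time courses.

The generator produces synthetic versions of the observables the analysis
pipeline consumes - sulfide (dissolved and acid-volatile), glycerol,
acetate, pH, OD600, dissolved metals, and dominance-skewed community
tables - with the statistical structure the estimators assume:

* a replicate-specific lag (lognormal inoculum heterogeneity emulating the
  uneven biomass of filter-wedge inocula), after which glycerol is turned
  over at a constant maximum rate: the latent sulfide production is
  genuinely zero-order, which is what the endpoint-secant rate estimator
  is built to recover;
* stoichiometric coupling: product yields per mole of glycerol come from
  the electron-balanced incomplete-oxidation reactions (sulfate pathway:
  1.5 acetate, 0.25 H2S, 0.5 H+ consumed; S(0) pathway: 1.5 acetate,
  1.0 H2S, no proton turnover), blended by the electron split
  ``f_sulfate``; mass and electron balances hold exactly at sigma = 0;
* sulfide routed through the Ksp-ordered precipitation titration each step
  (As2S3, then ZnS, then FeS), so dissolved metals fall sequentially while
  acid-volatile sulfide (dissolved + fresh metal-sulfide) accumulates;
* a beta-buffered pH that rises with proton consumption, an aluminium sink
  that activates above a pH threshold (hydroxide formation, outside the
  sulfide titration), and independent Gaussian observation noise truncated
  at zero.

S(0)-only microcosms are modelled as a low-rate, carbon-limited endogenous
pathway (slight alkalinity, small extent) rather than disproportionation,
matching their near-inactive observed behaviour without asserting
mechanism. Every run emits a latent truth record (injected lag, injected
zero-order rate, pathway split, noiseless state trajectories) for
parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from importlib import resources

from . import chemistry, geochemistry, stoichiometry
from .community import AbundanceTable
from .kinetics import MicrocosmSeries

__all__ = [
    "TreatmentConfig",
    "SimParams",
    "SimOutput",
    "media_metal_pool",
    "default_treatments",
    "default_params",
    "simulate_microcosm",
    "generate_replicate_set",
    "default_group_profiles",
    "generate_community_table",
]


def _coupled_yields():
    reg = stoichiometry.half_reaction_registry()
    r2 = stoichiometry.couple(reg["glycerol_to_acetate"], reg["sulfate_to_H2S"], "R2")
    r4 = stoichiometry.couple(reg["glycerol_to_acetate"], reg["S0_to_H2S"], "R4")
    return stoichiometry.yields(r2), stoichiometry.yields(r4)


_Y2, _Y4 = None, None


def _pathway_yields():
    global _Y2, _Y4
    if _Y2 is None:
        _Y2, _Y4 = _coupled_yields()
    return _Y2, _Y4


def media_metal_pool() -> dict[str, float]:
    """Starting dissolved metal(loid) pool (mol/L) from the media recipe."""
    text = resources.files("sulfidogen.data").joinpath("media.yaml").read_text()
    recipe = yaml.safe_load(text)["media"]
    pool = {}
    for metal, salt in [
        ("Fe", "FeSO4.7H2O"),
        ("Zn", "ZnSO4.7H2O"),
        ("As", "NaH2AsO4"),
        ("Al", "Al2(SO4)3.H2O"),
    ]:
        sp = chemistry.Species.from_formula(salt, salt)
        molarity = chemistry.mass_concentration_to_molarity(recipe[salt], sp)
        pool[metal] = molarity * sp.formula.get(metal, 0.0)
    return pool


@dataclass
class TreatmentConfig:
    """Substrate amendment and starting chemistry of one treatment."""

    label: str
    glycerol0_mM: float = 0.0
    s0_present: bool = False
    inoculated: bool = True
    pH0: float = 4.2
    metals_mol_per_L: dict[str, float] = field(default_factory=media_metal_pool)

    def __post_init__(self):
        if self.glycerol0_mM < 0:
            raise ValueError("glycerol must be non-negative")
        if not (0 < self.pH0 < 14):
            raise ValueError("pH0 out of range")


@dataclass
class SimParams:
    """Simulator parameters (defaults are the study-condition calibration).

    Units: days for times, mM/d for turnover, mol H+ per L per pH unit for
    the buffer capacity beta. ``noise_sigma`` is per recorded analyte.
    """

    lag_mean_d: float = 13.0
    inoculum_spread: float = 2.0  # sigma of ln(inoculum_factor)
    mu_per_d: float = 1.5  # biomass growth rate (OD ramp only)
    qmax_mM_d: float = 0.35  # max glycerol turnover
    f_sulfate: float = 1.0  # electron fraction to sulfate (vs S0)
    beta_mol_per_pH: float = 1.6e-3  # buffer capacity
    s0_endogenous_rate_mM_d: float = 0.005
    s0_endogenous_extent_mM: float = 0.2
    s0_endogenous_alkalinity: float = 0.5  # mol H+ consumed per mol sulfide
    od_per_mM_glycerol: float = 0.07
    al_pH_threshold: float = 5.0
    al_removal_rate_per_d: float = 0.5
    dt_d: float = 0.25
    duration_d: float = 25.0
    obs_interval_d: float = 1.0
    noise_sigma: dict = field(
        default_factory=lambda: {
            "sulfide_uM": 10.0,
            "sulfide_dissolved_uM": 2.0,
            "glycerol_mM": 0.10,
            "acetate_mM": 0.05,
            "pH": 0.03,
            "OD600": 0.01,
            "Fe_mM": 0.10,
            "Zn_mM": 0.005,
            "As_mM": 0.0005,
            "Al_mM": 0.005,
        }
    )

    def __post_init__(self):
        if not (0.0 <= self.f_sulfate <= 1.0):
            raise ValueError("f_sulfate must be in [0, 1]")
        for name, v in (
            ("qmax_mM_d", self.qmax_mM_d),
            ("mu_per_d", self.mu_per_d),
            ("dt_d", self.dt_d),
            ("duration_d", self.duration_d),
        ):
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(s < 0 for s in self.noise_sigma.values()):
            raise ValueError("noise sigmas must be non-negative")


def default_treatments() -> dict[str, TreatmentConfig]:
    """The four study treatments plus the uninoculated control."""
    return {
        "Gly": TreatmentConfig(label="Gly", glycerol0_mM=5.0),
        "Gly+S": TreatmentConfig(label="Gly+S", glycerol0_mM=5.0, s0_present=True),
        "S0": TreatmentConfig(label="S0", s0_present=True),
        "control": TreatmentConfig(label="control"),
        "uninoculated": TreatmentConfig(
            label="uninoculated", glycerol0_mM=5.0, inoculated=False
        ),
    }


def default_params(label: str) -> SimParams:
    """Per-treatment default parameters, calibrated qualitatively to the
    observed ordering (Gly+S: shorter lag, faster and larger sulfide
    production than Gly; S(0)-only near-inactive)."""
    if label == "Gly+S":
        return SimParams(lag_mean_d=8.0, f_sulfate=0.8)
    if label == "S0":
        return SimParams(lag_mean_d=18.0, qmax_mM_d=0.0)
    return SimParams()


@dataclass
class SimOutput:
    """Observed (noisy) series plus the latent truth of one simulated run."""

    microcosm_id: str
    treatment: str
    generation: int
    times_d: np.ndarray
    observed: dict[str, np.ndarray]  # analyte -> values on times_d
    latent: dict[str, np.ndarray]  # noiseless trajectories + balances
    truth: dict  # injected lag, rate, split, inoculum factor

    def to_series(self) -> MicrocosmSeries:
        analytes = {
            name: np.column_stack([self.times_d, vals])
            for name, vals in self.observed.items()
        }
        return MicrocosmSeries(
            microcosm_id=self.microcosm_id,
            treatment=self.treatment,
            generation=self.generation,
            analytes=analytes,
        )

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for analyte, vals in self.observed.items():
            unit = analyte.rsplit("_", 1)[-1] if "_" in analyte else ""
            name = analyte.rsplit("_", 1)[0] if unit in ("uM", "mM") else analyte
            for t, v in zip(self.times_d, vals):
                rows.append(
                    {
                        "microcosm_id": self.microcosm_id,
                        "treatment": self.treatment,
                        "generation": self.generation,
                        "analyte": name,
                        "time_d": t,
                        "value": v,
                        "unit": unit or "dimensionless",
                    }
                )
        return pd.DataFrame(rows)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_microcosm(
    treatment: TreatmentConfig,
    params: SimParams,
    seed,
    microcosm_id: str | None = None,
    generation: int = 1,
) -> SimOutput:
    """Simulate one microcosm; deterministic given (treatment, params, seed)."""
    rng = _rng(seed)
    y2, y4 = _pathway_yields()
    minerals = geochemistry.load_minerals()

    # replicate-level heterogeneity: lognormal inoculum factor; more
    # inoculum shortens the lag through the growth rate
    z = rng.standard_normal()
    inoc = float(np.exp(params.inoculum_spread * z)) if treatment.inoculated else 0.0
    if treatment.inoculated and params.mu_per_d > 0:
        lag = max(0.0, params.lag_mean_d - np.log(max(inoc, 1e-12)) / params.mu_per_d)
    else:
        lag = params.lag_mean_d

    f = params.f_sulfate if treatment.s0_present else 1.0
    blended_sulfide_yield = y2.sulfide_yield * f + y4.sulfide_yield * (1.0 - f)
    acetate_yield = y2.acetate_yield * f + y4.acetate_yield * (1.0 - f)
    protons_per_gly = y2.protons_consumed * f + y4.protons_consumed * (1.0 - f)
    sulfate_per_gly = y2.sulfate_consumed * f
    s0_per_gly = y4.S0_consumed * (1.0 - f)

    glycerol_pathway = treatment.inoculated and treatment.glycerol0_mM > 0
    endogenous = (
        treatment.inoculated and treatment.s0_present and treatment.glycerol0_mM == 0
    )

    # state (concentrations in mM except the metal pool, mol/L)
    G = treatment.glycerol0_mM
    A = 0.0
    S_diss = 0.0
    S_endog = 0.0
    pH = treatment.pH0
    pool = geochemistry.MetalPool(dict(treatment.metals_mol_per_L))
    consumed = 0.0
    sulfate_used = 0.0
    s0_used = 0.0
    produced = 0.0

    n_steps = int(round(params.duration_d / params.dt_d))
    obs_every = max(1, int(round(params.obs_interval_d / params.dt_d)))
    times, latent_rows = [], []

    def _precip_sulfide_mM() -> float:
        tot = 0.0
        for m in minerals:
            tot += pool.precipitated.get(m.name, 0.0) * m.sulfide_per_formula
        return tot * 1e3

    def _biomass(t: float) -> float:
        if not treatment.inoculated or t < lag:
            return 0.0
        return min(1.0, 0.05 * np.exp(params.mu_per_d * (t - lag)))

    for step in range(n_steps + 1):
        t = step * params.dt_d
        if step > 0:
            dS = 0.0
            dH_consumed = 0.0  # mol/L
            if glycerol_pathway and t > lag and G > 0:
                dG = min(params.qmax_mM_d * params.dt_d, G)
                G -= dG
                consumed += dG
                A += acetate_yield * dG
                dS = blended_sulfide_yield * dG
                sulfate_used += sulfate_per_gly * dG
                s0_used += s0_per_gly * dG
                dH_consumed = protons_per_gly * dG * 1e-3
            elif endogenous and t > lag and S_endog < params.s0_endogenous_extent_mM:
                dS = min(
                    params.s0_endogenous_rate_mM_d * params.dt_d,
                    params.s0_endogenous_extent_mM - S_endog,
                )
                S_endog += dS
                s0_used += dS
                dH_consumed = params.s0_endogenous_alkalinity * dS * 1e-3
            produced += dS
            pool, resid = geochemistry.titrate_sulfide(
                pool, (S_diss + dS) * 1e-3, minerals
            )
            S_diss = resid * 1e3
            pH = pH + dH_consumed / params.beta_mol_per_pH
            if pH > params.al_pH_threshold and pool.dissolved.get("Al", 0.0) > 0:
                pool.dissolved["Al"] *= float(
                    np.exp(-params.al_removal_rate_per_d * params.dt_d)
                )
        if not np.isfinite([G, A, S_diss, pH]).all():
            raise RuntimeError(f"non-finite simulator state at t={t:.2f} d")
        if step % obs_every == 0:
            times.append(t)
            latent_rows.append(
                {
                    "sulfide_uM": (S_diss + _precip_sulfide_mM()) * 1e3,
                    "sulfide_dissolved_uM": S_diss * 1e3,
                    "glycerol_mM": G,
                    "acetate_mM": A,
                    "pH": pH,
                    "OD600": params.od_per_mM_glycerol * consumed * _biomass(t)
                    + (0.01 if endogenous and t > lag else 0.0),
                    "Fe_mM": pool.dissolved.get("Fe", 0.0) * 1e3,
                    "Zn_mM": pool.dissolved.get("Zn", 0.0) * 1e3,
                    "As_mM": pool.dissolved.get("As", 0.0) * 1e3,
                    "Al_mM": pool.dissolved.get("Al", 0.0) * 1e3,
                    "glycerol_consumed_mM": consumed,
                    "sulfide_produced_mM": produced,
                    "sulfate_consumed_mM": sulfate_used,
                    "S0_consumed_mM": s0_used,
                }
            )

    times = np.asarray(times)
    latent = {k: np.array([r[k] for r in latent_rows]) for k in latent_rows[0]}
    observed = {}
    for name in (
        "sulfide_uM",
        "sulfide_dissolved_uM",
        "glycerol_mM",
        "acetate_mM",
        "pH",
        "OD600",
        "Fe_mM",
        "Zn_mM",
        "As_mM",
        "Al_mM",
    ):
        sigma = params.noise_sigma.get(name, 0.0)
        noise = rng.normal(0.0, sigma, size=len(times)) if sigma > 0 else 0.0
        observed[name] = np.maximum(latent[name] + noise, 0.0)

    injected_rate = (
        params.qmax_mM_d * blended_sulfide_yield * 1e3
        if glycerol_pathway
        else (params.s0_endogenous_rate_mM_d * 1e3 if endogenous else 0.0)
    )
    truth = {
        "lag_d": lag if treatment.inoculated else None,
        "zero_order_rate_uM_d": injected_rate,
        "f_sulfate": f if glycerol_pathway else None,
        "inoculum_factor": inoc,
        "blended_sulfide_yield": blended_sulfide_yield if glycerol_pathway else None,
    }
    return SimOutput(
        microcosm_id=microcosm_id or f"{treatment.label}-G{generation}",
        treatment=treatment.label,
        generation=generation,
        times_d=times,
        observed=observed,
        latent=latent,
        truth=truth,
    )


def generate_replicate_set(
    treatment: TreatmentConfig,
    params: SimParams,
    n_replicates: int,
    seed: int,
    generation: int = 1,
) -> list[SimOutput]:
    """Simulate n replicates; replicate k's stream is keyed by (seed, k) so
    it is stable when n changes."""
    if n_replicates < 1:
        raise ValueError("need n_replicates >= 1")
    out = []
    for k in range(n_replicates):
        rng = np.random.default_rng([int(seed) % (2**31), k])
        out.append(
            simulate_microcosm(
                treatment,
                params,
                rng,
                microcosm_id=f"{treatment.label}-G{generation}_{k + 1}",
                generation=generation,
            )
        )
    return out


def default_group_profiles() -> dict[str, dict[str, float]]:
    """Planted community profiles per treatment group.

    Glycerol-amended groups carry a dominant sulfate-reducer (~0.86 for Gly,
    ~0.95 for Gly+S, matching the observed 76-96% and 93-99% dominance
    ranges); the S(0)-only group is comparatively even; the field group is
    a moderately diverse inoculum-like profile.
    """
    return {
        "Gly": {
            "Desulfosporosinus": 0.86,
            "Paludibacteraceae": 0.08,
            "Desulfitobacterium": 0.013,
            "Thermoplasmatales": 0.02,
            "Thermodesulfovibrionia": 0.01,
            "Desulfomonile": 0.007,
            "other": 0.01,
        },
        "Gly+S": {
            "Desulfosporosinus": 0.95,
            "Desulfitobacterium": 0.03,
            "Paludibacteraceae": 0.001,
            "Thermoplasmatales": 0.009,
            "other": 0.01,
        },
        "S0": {
            "Cellulomonas": 0.18,
            "Desulfitobacterium": 0.16,
            "Desulfomonile": 0.15,
            "Sulfuriferula": 0.14,
            "Desulfurispora": 0.10,
            "Ignavibacteria": 0.10,
            "Thermoplasmatales": 0.09,
            "other": 0.08,
        },
        "field": {
            "Thermoplasmatales": 0.30,
            "Thermodesulfovibrionia": 0.15,
            "Parcubacteria": 0.08,
            "Paludibacteraceae": 0.03,
            "Desulfosporosinus": 0.02,
            "Desulfomonile": 0.01,
            "Cellulomonas": 0.05,
            "Ignavibacteria": 0.05,
            "other": 0.31,
        },
    }


def generate_community_table(
    group_profiles: dict[str, dict[str, float]] | None = None,
    n_samples: int = 3,
    depth: int = 20000,
    concentration: float = 200.0,
    seed: int = 0,
) -> AbundanceTable:
    """Dirichlet-multinomial community tables with planted group structure.

    Each sample's taxon proportions are drawn from a Dirichlet centred on
    its group profile (``concentration`` controls overdispersion: higher is
    tighter) and counts from a multinomial at ``depth``. Taxa with zero
    profile probability stay structurally absent.
    """
    profiles = group_profiles or default_group_profiles()
    rng = np.random.default_rng(seed)
    taxa = sorted({t for prof in profiles.values() for t in prof})
    counts, sample_ids, groups = [], [], []
    for group in profiles:
        p = np.array([profiles[group].get(t, 0.0) for t in taxa])
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"profile for group {group!r} does not sum to 1")
        support = p > 0
        for i in range(n_samples):
            q = np.zeros_like(p)
            q[support] = rng.dirichlet(concentration * p[support])
            counts.append(rng.multinomial(depth, q))
            sample_ids.append(f"{group}_{i + 1}")
            groups.append(group)
    return AbundanceTable(
        counts=np.array(counts, dtype=float),
        sample_ids=sample_ids,
        taxon_ids=list(taxa),
        groups=groups,
    )
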