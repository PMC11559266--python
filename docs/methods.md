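# Methods

This note documents the models, data and numerical choices behind
`sulfidogen`, in the order the pipeline uses them.

## Chemical data model

Species are element-count maps with integer charge and a phase drawn from
{aqueous, gas, liquid, solid}. The formula grammar covers element symbols
with (possibly fractional) counts, parenthesised groups, hydrate suffixes
("FeSO4·7H2O"; "·", "." and "*" all accepted, since the literature typesets
the hydrate dot inconsistently) and trailing ionic charges ("SO4^2-",
"H+"). The electron is a first-class pseudo-species (no elements, charge
−1, mass 0) so half-reactions balance like any other reaction.

Atomic weights are shipped as static package data (IUPAC 2021 conventional
values) so molar masses are reproducible offline; e.g. FeSO₄·7H₂O is
278.01 g/mol, making the 3000 mg/L recipe dose 10.79 mM Fe(II). Note that
descriptions of this medium sometimes round this to "12 mM"; the package
reports the computed value.

Balance checking reports per-element and charge imbalance (products minus
reactants) and flags a reaction balanced when every imbalance is below
1e-9; fractional coefficients (0.25, 1.75, 3.5 …) are first-class.

## Formation-energy table and the reaction set

The packaged `thermo.csv` lists ΔG⁰f (and, for the inorganic species,
ΔH⁰f) at 298.15 K with a source string per record. Inorganic values
(SO₄²⁻ −744.63, H₂S(aq) −27.87, CO₂(g) −394.36, H₂O(l) −237.17 kJ/mol) and
acetate follow Thauer's classical bioenergetics compilation; undissociated
acetic acid is derived from the acetate value and pKa 4.76 (−396.58).

**Glycerol deserves a caveat.** Compilations disagree by ~50 kJ/mol:
Thauer-style tables give −488.5 kJ/mol for aqueous glycerol, while
HKF-based compilations (Amend & Shock style) give ≈ −438.5. The package
ships −438.5, which makes the computed energies of the four glycerol
couplings internally consistent with the widely used reference values for
this system (−439, −214, −228, −184 kJ/mol glycerol); with the Thauer
value every glycerol reaction shifts +50 kJ/mol. The choice is recorded in
the data file's source string; swap the value there to adopt the other
convention. No conclusions in this package depend on which compilation is
used — all four couplings are strongly exergonic either way.

**The disproportionation reaction is shipped balanced.** Per mole of S(0),
sulfur disproportionation is 4 S(0) + 4 H₂O → SO₄²⁻ + 3 H₂S + 2 H⁺, i.e.
0.25 SO₄²⁻ + 0.5 H⁺ + **0.75** H₂S per S(0). A common typographical variant
writes the H₂S coefficient as 1, which does not conserve S or H; the
energies computed here (+30.1 kJ/mol standard, −7.9 kJ/mol in situ at
291 K) require the balanced 0.75 coefficient, and the package's balance
invariant enforces it.

## Activity conventions and the reaction quotient

Molar concentrations are used directly as activities (activity
coefficients = 1), {H⁺} = 10^−pH, gases enter as partial pressure in bar,
and solids and liquid water sit at unit activity. No ionic-strength
correction (Davies/Debye–Hückel) is applied; at the ~0.1 M ionic strength
of these media that approximation costs a few kJ/mol, which is why in-situ
energies should be read with ±10–15 kJ/mol in mind. The packaged starting
condition set is 291 K (18 °C), pH 4.2, [SO₄²⁻] 0.14 M, [glycerol] 5 mM,
[acetate] 5 µM, [H₂S] 1 µM, CO₂ at 0.05 bar.

## Temperature adjustment

The 298.15 → 291 K adjustment uses Gibbs–Helmholtz with a
temperature-independent reaction enthalpy, ΔG(T) = ΔH − (T/T_ref)(ΔH −
ΔG(T_ref)), whenever every species in the reaction has a formation
enthalpy; otherwise ΔG⁰ is carried over unchanged. Enthalpies are shipped
only for the inorganic species, so in practice R5 gets the
Gibbs–Helmholtz correction (≈ 0.03 kJ/mol at 7 K) and the glycerol/acetate
reactions use the constant-ΔG⁰ fallback — defensible because over 7 K the
correction is far smaller than the formation-energy uncertainty. Both
behaviours are exposed through `temperature_adjust` and the
`use_enthalpy` flag.

## Electron-balance coupling

Donor half-reactions are built from formal mean carbon oxidation states
(H = +1, O = −2, carbon carries the remainder): glycerol (C at −2/3)
releases 14 e⁻ to CO₂ and 2 e⁻ to 1.5 acetate; acetate releases 8 e⁻ to
CO₂. Oxygen is balanced with water, hydrogen with protons, charge with
electrons. Coupling scales the acceptor (SO₄²⁻/H₂S: 8 e⁻; S(0)/H₂S: 2 e⁻)
by the electron ratio and cancels the electron. This reproduces the
coupled reaction set exactly (1.75 SO₄²⁻ and 3.5 H⁺ for complete oxidation
on sulfate; 7 S(0) for complete oxidation on sulfur; 0.25 vs 1.0 mol
sulfide per glycerol for the incomplete pathways). A structure-aware
oxidation-state engine is deliberately out of scope; the formal rule
suffices for the species here.

Note one stoichiometric subtlety: prose descriptions of the incomplete
sulfate pathway sometimes quote "0.5 mol sulfide per mol glycerol", which
is inconsistent with the 8-electron sulfate balance (2 e⁻ released / 8 e⁻
per sulfate = 0.25). The package follows the electron balance.

Nutrient demand uses the biomass composition C₅H₇O₂N₁P₀.₁: N = C/5,
P = C/50 (molar N:P = 10).

## Precipitation titration

Metal-sulfide removal is modelled as a sequential, stoichiometric
(threshold) titration, not a full equilibrium speciation: each mole of
produced S(-II) precipitates the least soluble mineral first until its
metal is exhausted, conserving mass per metal and for sulfur. Rationale:
the observed removal ordering is argued from solubility products, and
acid-volatile-sulfide measurements conflate dissolved and labile solid
phases, so a saturation-index kinetic model would add parameters without
adding testable structure.

Minerals are ranked by **log Ksp per mole of metal** in the formula unit.
Some normalisation is required to compare the 2:3 As₂S₃ with the 1:1
monosulfides; per-metal normalisation (−35.9 < −24.7 < −17.3) reproduces
the observed As → Zn → Fe sequence, whereas per-sulfide normalisation
(−23.9 vs −24.7) would invert the As/Zn order. Arsenic is treated as
As(III) forming As₂S₃ with any As(V) reduction assumed complete
beforehand; Zn(As)S co-precipitation is represented only through ordering.
Aluminium is not a sulfide former and is handled in the simulator as a
separate pH-threshold sink (hydroxide formation above pH ≈ 5).

## Kinetics extraction

The production window opens at the first sampling interval whose
finite-difference rate exceeds 0.05 mM/d (50 µM/d) and closes with the
first contiguous run of qualifying intervals; the zero-order rate is the
endpoint secant over the window and the lag time is the window start. The
threshold is configurable but defaults to the stated 0.05 mM/d. The
endpoint secant (not least squares) is intentional: windows typically
contain 2–4 points, where a regression adds variance without robustness.
Lag is defined as window start because no separate operational lag
definition exists for these systems; it ties the lag to the same
threshold as the rate. Replicates are always reported unaveraged.
Internal units are µM and days; readers convert mM.

## Simulator

Discrete-time explicit stepping (default Δt = 0.25 d, 25 d duration,
daily observations) rather than an ODE solver: observation cadence is
daily-scale and the threshold precipitation model removes stiffness. Per
step, after the replicate lag: glycerol is turned over at the maximum rate
q_max (default 0.35 mM/d); products follow the electron-balanced yields
blended by f_sulfate (electron fraction to sulfate; forced to 1 without
added S(0), default 0.8 with it); sulfide passes through the titration;
pH rises by (protons consumed)/β with buffer capacity β = 1.6 × 10⁻³ mol
H⁺/L per pH unit (chosen so full consumption of 5 mM glycerol on the
sulfate pathway raises pH from 4.2 to ≈ 5.8, the observed span).

The latent sulfide production is genuinely zero-order (step onset at the
lag, constant rate until substrate exhaustion). This is a deliberate
modelling choice, not a simplification of convenience: the zero-order rate
law is what such microcosm data support, and it makes the estimator's
target well-defined. The exponential-growth ramp appears only in the
OD600 observable. Replicate heterogeneity enters through a lognormal
inoculum factor (σ_ln = 2 by default) that shortens or lengthens the lag
via the growth rate (lag = lag_mean − ln(factor)/µ); per-treatment lag
means (13 d glycerol-only, 8 d glycerol+sulfur, 18 d sulfur-only) and
turnover defaults qualitatively match the observed first-generation
ordering and magnitudes — they are calibrations of regime, never fits.
S(0)-only microcosms get a low-rate (5 µM/d), carbon-limited (200 µM)
endogenous pathway with slight alkalinity: their near-inactivity is
reproduced without asserting a disproportionation mechanism. Observation
noise is independent Gaussian per analyte (σ = 10 µM for sulfide),
truncated at zero, added last. Replicate k's random stream is keyed by
(master seed, k), so it is stable when the replicate count changes.

What the generator does **not** emulate: thermodynamic rate limitation,
sulfide toxicity feedback, pyrite/greigite transformation, sorption,
multi-generation transfer dynamics, or realistic assay artefacts. Passing
parameter-recovery tests on this generator therefore demonstrates that the
estimators are consistent with their own assumptions (zero-order kinetics,
threshold windows, Gaussian noise), not that real microcosm data satisfy
those assumptions.

Community tables are Dirichlet-multinomial draws around planted group
profiles (dominant taxon ≈ 0.86 in glycerol-only, ≈ 0.95 in
glycerol+sulfur groups, an even profile in sulfur-only, a diverse
field-like inoculum), at default depth 20 000 and concentration 200; taxa
with zero profile probability stay structurally absent.

## Community metrics

Shannon entropy is natural-log by default (a `base` flag is provided);
Bray–Curtis is Σ|x−y|/Σ(x+y) on raw counts; PCoA is Gower double-centring
of −½D² followed by a symmetric eigendecomposition, coordinates scaled by
√λ over positive eigenvalues only. Negative eigenvalues (non-Euclidean
dissimilarities) are retained and reported, with no Lingoes/Cailliez
correction, and proportion-explained is computed over the positive part.
Rarefaction is available as a seeded option but is not applied by default.
An eigenvector's sign is arbitrary; tests compare embeddings up to
per-axis sign.

## Numerical choices and degenerate inputs

Balance tolerance 1e-9 on coefficient arithmetic; R = 8.314 × 10⁻³
kJ/mol/K; °C converted with 273.15. Zero-sum abundance rows, duplicate
timestamps, negative concentrations, unknown units/analytes and
unbalanceable couplings raise (or are rejected row-wise with reasons, for
file input); titration of zero sulfide is the identity; an empty
production window reports rate 0 and lag "not detected" rather than
raising. Ties in mineral ranking break alphabetically. All randomness
descends from explicit seeds; no global random state is used.

## Problem sizes

Default test and acceptance runs use 200 simulated replicates for rate
recovery, 100 seeds for treatment-ordering comparisons, 50 seeds for
community contrasts, and ≤ 12-sample community tables — sizes chosen to
make Monte-Carlo assertions stable at the asserted margins.

## Known limitations

- No aqueous speciation of sulfide (H₂S/HS⁻) or ionic-strength
  corrections; in-situ energies carry ±10–15 kJ/mol of data-source and
  activity-model uncertainty.
- The titration has no kinetics: precipitation is instantaneous and
  complete within a step.
- The formation energy of aqueous glycerol is compilation-dependent at the
  50 kJ/mol level (see above); standard-state energies of R1–R4 inherit
  that uncertainty wholesale.
- Lag and rate definitions are threshold-based; data sampled more coarsely
  than the production window will bias the rate downward.
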