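# sulfidogen

Quantitative toolkit for **microbially driven sulfide production
(biosulfidogenesis) in acidic, metal-rich waters** — the chemistry that
underpins bioremediation of acidic pit lakes, where stimulating
sulfate-reducing bacteria precipitates dissolved Fe, Zn and As as
low-solubility sulfide minerals while neutralising acidity.

It is written for geomicrobiologists and environmental engineers who design
or analyse enrichment/microcosm experiments of this kind and want the
desk-side calculations — reaction energetics, stoichiometric expectations,
speciation, precipitation ordering, rate extraction, community summaries —
as tested, scriptable code rather than spreadsheet arithmetic.

## What it computes

**Bioenergetics.** For any reaction with stoichiometric coefficients
$\nu_i$, the standard-state energy $\Delta G_r^0 = \sum_i \nu_i \Delta
G_{f,i}^0$ and the in-situ energy

$$\Delta G_r' = \Delta G_r^0(T) + RT\ln Q,\qquad Q=\prod_i a_i^{\nu_i},$$

per mole of a reference substrate, with molar concentrations as activities,
$\{H^+\}=10^{-\mathrm{pH}}$, gases in bar, solids/water at unit activity.
The packaged reaction set covers complete/incomplete glycerol oxidation on
sulfate or elemental sulfur (R1–R4) and S(0) disproportionation (R5).

**Stoichiometry.** Coupled catabolic reactions are assembled from half
reactions by electron balance (formal carbon oxidation states; sulfate
accepts 8 e⁻, S(0) accepts 2 e⁻), giving per-substrate yields of sulfide,
acetate and alkalinity — e.g. incomplete glycerol oxidation yields 0.25 mol
H₂S/mol on sulfate but 1.0 mol H₂S/mol on S(0), a 4× difference.

**Geochemistry.** Henderson–Hasselbalch speciation (protonated acetate is
15.4 % at pH 5.5, pKa 4.76) and a Ksp-ranked sequential sulfide titration
that removes As₂S₃ (log Ksp −71.8), then ZnS (−24.7), then FeS (−17.3),
conserving mass per metal.

**Kinetics.** Lag time, maximum zero-order sulfide production rate and
extent from time series, using a 0.05 mM/d rate threshold to open/close the
production window and an endpoint-secant rate (deliberately not a
regression — typically only 2–4 points fall in the window).

**Simulation & community metrics.** A forward microcosm simulator
(lag → zero-order turnover → stoichiometric products → precipitation →
buffered pH, plus replicate heterogeneity and observation noise) generates
every input the analysis needs, including Dirichlet-multinomial community
tables; Shannon, Bray–Curtis and classical PCoA are implemented from first
principles.

## Worked example

```python
from sulfidogen import bioenergetics as bio, simulate as sim, kinetics as kin

print(bio.table2_analogue()[["reaction", "dG0_298K_kJ_per_mol",
                             "dG_insitu_291K_kJ_per_mol", "per_mol"]].round(2))

outs = []
for label in ("Gly", "Gly+S", "S0"):
    outs += sim.generate_replicate_set(
        sim.default_treatments()[label], sim.default_params(label), 2, seed=1)
print(kin.summarize([o.to_series() for o in outs]).round(2))
```

prints

```
reaction  dG0_298K_kJ_per_mol  dG_insitu_291K_kJ_per_mol  per_mol
      R1              -438.93                    -416.13 glycerol
      R2              -214.35                    -241.30 glycerol
      R3              -228.16                    -471.06 glycerol
      R4              -184.24                    -249.14 glycerol
      R5                30.11                      -7.88       S0

microcosm_id treatment  generation  lag_days  max_rate_uM_d  max_extent_uM  ...
    Gly-G1_1       Gly           1      13.0          87.76        1092.00
    Gly-G1_2       Gly           1      12.0          87.45        1136.87
  Gly+S-G1_1     Gly+S           1       7.0         133.76        2010.07
  Gly+S-G1_2     Gly+S           1       7.0         133.18        2021.24
     S0-G1_1        S0           1       NaN           0.00          35.75
     S0-G1_2        S0           1       NaN           0.00          59.99
```

Reading the energy table: all four glycerol couplings are strongly
favourable; S(0) disproportionation flips from unfavourable at standard
state (+30.1 kJ/mol) to slightly favourable (−7.9 kJ/mol) under the dilute
starting conditions — which is why a trace of sulfide can appear even in
sulfur-only incubations. The kinetics table shows the simulated
glycerol+sulfur microcosms starting earlier (lag 7 d vs 12–13 d) and
producing sulfide faster and to greater extent than glycerol alone, the
ordering the thermodynamics predicts; sulfur-only microcosms never cross
the 50 µM/d production threshold (lag NaN, rate 0).

A CLI mirrors the library: `sulfidogen thermo`, `sulfidogen couple
glycerol_to_acetate S0_to_H2S`, `sulfidogen titrate`, `sulfidogen
kinetics`, `sulfidogen simulate`, `sulfidogen community`, `sulfidogen run`.

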