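# Candidate catabolic reactions for glycerol/sulfur amended acidic pit-lake
# microcosms. Species names refer to entries in thermo.csv; coefficients are
# signed (negative = reactant) and normalised per mole of the reference
# substrate. R1/R2: complete/incomplete glycerol oxidation on sulfate;
# R3/R4: the same on elemental sulfur; R5: S(0) disproportionation.
reactions:
  R1:
    reference_substrate: glycerol
    terms:
      glycerol: -1.0
      sulfate: -1.75
      proton: -3.5
      H2S: 1.75
      CO2: 3.0
      water: 4.0
  R2:
    reference_substrate: glycerol
    terms:
      glycerol: -1.0
      sulfate: -0.25
      proton: -0.5
      acetic_acid: 1.5
      H2S: 0.25
      water: 1.0
  R3:
    reference_substrate: glycerol
    terms:
      glycerol: -1.0
      S0: -7.0
      water: -3.0
      CO2: 3.0
      H2S: 7.0
  R4:
    reference_substrate: glycerol
    terms:
      glycerol: -1.0
      S0: -1.0
      acetic_acid: 1.5
      H2S: 1.0
  # disproportionation per mole S(0); note the 0.75 H2S coefficient is
  # forced by sulfur/hydrogen balance (4 S + 4 H2O -> SO4^2- + 3 H2S + 2 H+)
  R5:
    reference_substrate: S0
    terms:
      S0: -1.0
      water: -1.0
      sulfate: 0.25
      proton: 0.5
      H2S: 0.75
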