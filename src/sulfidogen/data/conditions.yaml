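# Starting conditions of the microcosm incubations (18 C = 291 K).
# Aqueous molar concentrations are used directly as activities (activity
# coefficients = 1); H+ activity is 10^-pH; gases enter as partial pressure
# in bar; solids and liquid water are at unit activity.
conditions:
  microcosm_start:
    temperature_K: 291.0
    pH: 4.2
    activities:
      glycerol: 5.0e-3
      sulfate: 0.14
      H2S: 1.0e-6
      acetic_acid: 5.0e-6
    gas_pressures:
      CO2: 0.05
    unit_activity:
      - S0
      - water
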