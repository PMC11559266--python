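# Synthetic deep-layer medium recipe (mg per litre unless noted). Formulas
# feed chemistry.mass_concentration_to_molarity to derive the starting metal
# pool and sulfate background of the simulator.
media:
  FeSO4.7H2O: 3000.0
  CaSO4.2H2O: 219.0
  MgSO4: 202.0
  NH4Cl: 69.5
  ZnSO4.7H2O: 48.0
  MnSO4.H2O: 35.8
  Al2(SO4)3.H2O: 34.0
  NaCl: 6.20
  NaH2AsO4: 3.82
  KCl: 0.97
  CoCl2.6H2O: 0.82
  NaHCO3: 0.57
  NaNO3: 0.43
  NiCl2.6H2O: 0.37
  CuSO4: 0.04
initial_pH: 4.2
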