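name,formula,phase,dGf0_kJ_mol,dHf0_kJ_mol,source
glycerol,C3H8O3,aqueous,-438.5,,"HKF-style aqueous value consistent with the reference reaction-energy set (cf. Amend & Shock 2001); Thauer et al. 1977 list -488.52, a 50 kJ/mol compilation discrepancy documented in docs/methods.md"
sulfate,SO4^2-,aqueous,-744.63,-909.27,"Thauer et al. 1977 (dG); NBS tables (dH)"
proton,H+,aqueous,0.0,0.0,"convention: aqueous H+ reference state"
H2S,H2S,aqueous,-27.87,-39.7,"Thauer et al. 1977 (dG); NBS tables (dH)"
H2S_gas,H2S,gas,-33.56,-20.6,"Thauer et al. 1977 (dG); NBS tables (dH)"
CO2,CO2,gas,-394.36,-393.51,"Thauer et al. 1977 (dG); CODATA (dH)"
water,H2O,liquid,-237.17,-285.83,"Thauer et al. 1977 (dG); CODATA (dH)"
acetic_acid,CH3COOH,aqueous,-396.58,,"Thauer et al. 1977 acetate (-369.41) + dissociation free energy at pKa 4.76"
acetate,CH3COO-,aqueous,-369.41,,"Thauer et al. 1977"
S0,S(0),solid,0.0,0.0,"element reference state (rhombic sulfur)"
electron,e-,aqueous,0.0,0.0,"convention: electron pseudo-species"
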