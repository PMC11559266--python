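# Metal-sulfide mineral constants used to rank and titrate precipitation.
# logKsp follows the dissolution convention (mineral <-> metal ion(s) +
# sulfide ion(s)); ranking for removal order is per mole of sulfide in the
# formula unit so unlike stoichiometries (As2S3 vs MeS) compare sensibly.
minerals:
  As2S3:
    metal: As
    logKsp: -71.8
    metal_per_formula: 2
    sulfide_per_formula: 3
  ZnS:
    metal: Zn
    logKsp: -24.7
    metal_per_formula: 1
    sulfide_per_formula: 1
  FeS:
    metal: Fe
    logKsp: -17.3
    metal_per_formula: 1
    sulfide_per_formula: 1
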