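name: 3d
reactants:
  - {name: 2-amino-5-nitrobenzophenone, formula: C13H10N2O3, equivalents: 1}
  - {name: 4,4'-bicyclohexanedione, formula: C12H18O2, equivalents: 1}
product:
  formula: C25H24N2O3
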