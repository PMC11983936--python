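name: 4b
reactants:
  - {name: 2-amino-5-chlorobenzophenone, formula: C13H10ClNO, equivalents: 2}
  - {name: 4,4'-bicyclohexanedione, formula: C12H18O2, equivalents: 1}
product:
  formula: C38H30Cl2N2
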