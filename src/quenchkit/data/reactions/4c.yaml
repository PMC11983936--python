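name: 4c
reactants:
  - {name: 2-amino-5-chloro-2'-chlorobenzophenone, formula: C13H9Cl2NO, equivalents: 2}
  - {name: 4,4'-bicyclohexanedione, formula: C12H18O2, equivalents: 1}
product:
  formula: C38H28Cl4N2
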