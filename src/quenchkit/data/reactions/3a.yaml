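# Friedlander condensation: 2-aminobenzophenone + 4,4'-bicyclohexanedione
# -> tetrahydroacridinyl cyclohexanone, losing 2 H2O.
name: 3a
reactants:
  - {name: 2-aminobenzophenone, formula: C13H11NO, equivalents: 1, mass_g: 0.5}
  - {name: 4,4'-bicyclohexanedione, formula: C12H18O2, equivalents: 1, mass_g: 0.49}
auxiliaries:
  - {name: conc. HCl, role: catalyst, mass_g: 0.59}
product:
  formula: C25H25NO
  mass_g: 0.4824
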