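# Dimer: 2 eq 2-aminobenzophenone + 1 eq 4,4'-bicyclohexanedione -> biacridine + 4 H2O.
name: 4a
reactants:
  - {name: 2-aminobenzophenone, formula: C13H11NO, equivalents: 2, mass_g: 2.03}
  - {name: 4,4'-bicyclohexanedione, formula: C12H18O2, equivalents: 1, mass_g: 1.0}
auxiliaries:
  - {name: conc. HCl, role: catalyst, mass_g: 0.59}
product:
  formula: C38H32N2
  mass_g: 0.9998
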