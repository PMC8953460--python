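# Hydroxyantazoline (M2), the para-hydroxylated metabolite of antazoline.
# All inputs are QSAR predictions (no in vitro data exist for the metabolite):
# logP/pKa from ChemAxon, fu and B/P from QSAR, total clearance from pkCSM.
# The acid pKa is assigned to the phenolic hydroxyl (10.3); the imidazoline
# base retains a pKa close to the parent's (9.2).
name: hydroxyantazoline
ionization_class: ampholyte
molecular_weight: 281.36      # g/mol
logP: 2.57
pKa_values:
  - {value: 10.3, role: acid}
  - {value: 9.2, role: base}
fu_plasma: 0.742
blood_plasma_ratio: 1.0
elimination:
  enzyme_pathways: []
  additional_systemic_clearance: 0.0
  total_systemic_clearance: 12.0   # L/h, plasma-referenced, no tracked products
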