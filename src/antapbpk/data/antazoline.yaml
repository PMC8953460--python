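# Antazoline (free base) model inputs.
# Phys-chem from public databases (PubChem/ALOGPS/ChemAxon averages); blood
# binding and recombinant-CYP intrinsic clearances from in vitro assays;
# additional systemic clearance from the clinical-vs-IVIVE clearance gap.
name: antazoline
ionization_class: monoprotic_base
molecular_weight: 265.35      # g/mol
logP: 3.16
pKa_values:
  - {value: 9.43, role: base}
fu_plasma: 0.586
blood_plasma_ratio: 1.18
fu_mic: 0.88
elimination:
  enzyme_pathways:
    # CYP2D6 turnover is split 1:1 between the hydroxy metabolite (M2) and
    # the N-dealkylated product (M1, tracked only as a mass sink).
    - {enzyme: CYP2D6, clint_per_pmol: 24.75, isef: 1.0, metabolite_fraction: 0.5}
    # CYP2C19 is assumed to form the same hydroxy metabolite.
    - {enzyme: CYP2C19, clint_per_pmol: 0.14, isef: 1.0, metabolite_fraction: 1.0}
  additional_systemic_clearance: 10.0   # L/h, plasma-referenced, non-CYP routes
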