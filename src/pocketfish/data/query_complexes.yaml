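# Aspirin/salicylate query complexes available in the PDB, grouped by protein
# family.  The redundancy rule keeps the first-listed complex per family, so
# the preferred member of each redundant pair is listed first (1OXR over 1TGM;
# 3GCL over 2QQT).
complexes:
  - {struct_id: 1OXR, ligand: AIN, family: "Phospholipase A2"}
  - {struct_id: 1TGM, ligand: AIN, family: "Phospholipase A2"}
  - {struct_id: 3GCL, ligand: AIN, family: "Lactoperoxidase"}
  - {struct_id: 2QQT, ligand: AIN, family: "Lactoperoxidase"}
  - {struct_id: 4NSB, ligand: AIN, family: "Chitinase-3-like protein 1"}
  - {struct_id: 3IAZ, ligand: AIN, family: "Lactotransferrin"}
  - {struct_id: 1PTH, ligand: SAL, family: "Prostaglandin G/H synthase"}
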