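# 6-iodouridine: moderately stable; carries the hydroxide SN2 side
# channel producing 6-hydroxyuridine + iodide.
compound: 6IUrd
full_name: 6-iodouridine
initial_concentration_M: 1.0e-3
residual_nucleoside_M: 2.4e-10
base_exchange:
  species: 6-iodouracil anion
  ddG_kcal_per_mol: 7.3
  reference_species: uracil
  reference_pKa: 9.45
  role: anionic_base
sugar_exchange:
  species: ribose oxocarbenium
  ddG_kcal_per_mol: 15.5
  reference_species: dimethoxymethanol
  reference_pKa: -5.7
  role: cationic_acid
dissociation_dG_act_kcal_per_mol: 24.1
sn2_channel:
  dG_kcal_per_mol: -72.3
  dG_act_kcal_per_mol: 11.8
thermo: {}
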