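# 6-iodo-2'-deoxyuridine: hydrolyses within seconds in water.
compound: 6IdU
full_name: 6-iodo-2'-deoxyuridine
initial_concentration_M: 1.0e-3
residual_nucleoside_M: 3.6e-10
base_exchange:
  species: 6-iodouracil anion
  ddG_kcal_per_mol: 7.3
  reference_species: uracil
  reference_pKa: 9.45
  role: anionic_base
sugar_exchange:
  species: 2'-deoxyribose oxocarbenium
  ddG_kcal_per_mol: 9.1
  reference_species: dimethoxymethanol
  reference_pKa: -5.7
  role: cationic_acid
dissociation_dG_act_kcal_per_mol: 18.0
sn2_channel: null
thermo: {}
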