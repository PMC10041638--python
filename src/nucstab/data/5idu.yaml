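# 5-iodo-2'-deoxyuridine: the stable 5-substituted reference compound.
compound: 5IdU
full_name: 5-iodo-2'-deoxyuridine
initial_concentration_M: 1.0e-3
# Residual nucleoside at equilibrium used to calibrate K_diss
# (the absolute dissociation free energy is not an input).
residual_nucleoside_M: 5.8e-4
base_exchange:
  species: 5-iodouracil anion
  ddG_kcal_per_mol: 4.1
  reference_species: uracil
  reference_pKa: 9.45
  role: anionic_base
sugar_exchange:
  species: 2'-deoxyribose oxocarbenium
  ddG_kcal_per_mol: 9.1
  reference_species: dimethoxymethanol
  reference_pKa: -5.7
  role: cationic_acid
dissociation_dG_act_kcal_per_mol: 30.5
sn2_channel: null
thermo: {}
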