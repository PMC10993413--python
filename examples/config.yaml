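# Reference analysis of a synthetic ligand-surface trajectory.
# Box in nm; all other lengths in Angstrom, times in ps, energies in kJ/mol.
schema_version: 1
seed: 3
surface:
  box_x_nm: 6.0
  box_y_nm: 6.0
  box_z_nm: 2.5
  n_cols: 12
  n_rows: 12
  ligand_fraction: 0.25
  tether_mode: flexible
potential:
  ion_carboxylate_well_depth: 10.0   # ~4 kBT: a small, tightly binding cation
  ion_carboxylate_well_width: 2.5
  ion_ion_repulsion_strength: 2.0
  ion_ion_repulsion_range: 2.0
  carboxylate_repulsion_strength: 1.0
  carboxylate_repulsion_range: 2.0
  wall_stiffness: 20.0
bd:
  ion_diffusivity_input: 0.1         # 1.0e-9 m^2/s
  headgroup_diffusivity_input: 0.05
  timestep: 0.05
  n_steps: 20000                     # 1 ns
  save_stride: 20
window:
  last_fraction: 0.5
cluster:
  cutoff: 4.0
  roles: [phenyl_C]
ion_cluster:
  cutoff: 5.0
density:
  bin_width: 0.25
  species: [ion, carboxylate_O]
binding:
  temperature: 300.0
rdf:
  layer: [6.0, 18.0]
  r_max: 12.0
  dr: 0.2
angles:
  contact_cutoff: 3.2
  bin_width_deg: 5.0
msd:
  layer: [6.0, 18.0]
  max_lag: 100
  min_duration: 10
paths:
  ions: [0]
  stride: 5
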