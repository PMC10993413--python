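# samsurf

Trajectory analysis of monovalent cations on ligand-functionalized
self-assembled monolayer (SAM) surfaces — the model geometry for
multimodal chromatography resins — plus a Brownian-dynamics generator
that produces synthetic trajectories with planted, analytically known
truths to validate every statistic end to end.

## Who this is for

Simulators of charged, ligand-bearing surfaces who need the standard
post-processing toolbox as tested, reusable code: how strongly do
counterions bind to the ligand layer, how do they cluster with the
ligands' charged groups, how are they ordered within the bound layer,
and how fast do they move while bound — and how all of that shifts
across the cation series (Li⁺ → Na⁺ → K⁺ → Cs⁺, the Hofmeister
ordering).

## What it computes

Given a trajectory of labeled particles (ions, phenyl carbons,
carboxylate carbon/oxygen, hydroxyl oxygens, sulfur anchors) in a
periodic slab box:

- **Cluster statistics** — single-linkage distance-cutoff clustering of
  ligand moieties under the minimum-image convention (phenyl rings at
  4 Å between ring carbons; carboxylates at 5 Å between any carboxylate
  atom; mixed ion–carboxylate clusters with per-cluster compositions),
  pooled into cluster-size distributions P(s) and mean sizes.
- **Density profiles and binding free energy** — z-resolved densities
  ρ(z) in atoms/Å³; the bound-layer edge z_int where ligand density
  vanishes; three-region partitioning from carboxylate-density
  inflections (or support); and the binding free energy

      ΔG_binding = −k_B T ln(p_bound / p_unbound),

  with p_bound the fraction of ion observations at z < z_int and
  z_max the box height (k_B T = 2.48 kJ/mol near room temperature).
- **Ordering** — ion–ion pair distributions restricted to the bound
  layer (raw pair density, or slab-corrected g(r) with analytic
  spherical-cap shell volumes), and the distribution of the
  ion–(carboxylate O)–(carboxylate C) angle over contact pairs.
- **Dynamics** — bound-layer lateral diffusivity from residence-segment
  MSD via the Einstein relation MSD(t) = 4 D t, with D in Å²/ps and
  ×10⁻⁹ m²/s (0.1 Å²/ps ≡ 1.0 × 10⁻⁹ m²/s), bulk-normalized ratios, and
  unwrapped single-ion path traces.

The synthetic generator builds the reference surface (528 strands on a
hexagonal-like lattice in a 110 × 104 Å box, 132 of them carrying a
charged ligand, hence 132 neutralizing cations) and propagates ions by
overdamped Langevin dynamics through smooth Gaussian wells, tethers and
walls, so the input diffusivity, Boltzmann occupancies and planted
cluster labels are exact ground truth. See `docs/methods.md` for the
model, conventions and limitations.

## Worked example

`examples/config.yaml` builds a 144-strand surface (36 charged ligands,
36 cations), runs 1 ns of Brownian dynamics with a 10 kJ/mol
ion–carboxylate well (≈ 4 k_BT — a small, tightly binding cation), and
analyzes the last half:

```bash
samsurf all examples/config.yaml --out out/
```

prints, among other things:

```
"binding": {
  "delta_G_kBT": -2.873089316747417,
  "delta_G_kJ_mol": -7.166458101166785,
  "p_bound": 0.9465,
  "z_int": 18.25
},
"cluster":     { "mean_size": 1.1175265412553548 },
"ion_cluster": { "mean_size": 3.1160737470786812 },
"msd":         { "D_A2_ps": 0.04335208101449374, "D_1e9_m2_s": 0.4335208101449374 }
```

Reading: 94.65% of ion observations sit below the bound-layer edge
(z_int = 18.25 Å, where the carboxylate density has decayed to 10⁻³ of
its peak), a binding free energy of −7.17 kJ/mol ≈ −2.9 k_BT; phenyl
rings barely cluster (mean 1.12, they carry no attraction here) while
ions and carboxylates form mixed clusters of mean size 3.12; and bound
ions diffuse at 0.43 × 10⁻⁹ m²/s, less than half their 1.0 × 10⁻⁹ m²/s
input diffusivity, because binding slows them. Full tables (cluster-size
distributions, density profiles, RDF, angle distribution, MSD curve,
paths) land as CSV next to `report.json`, which is byte-identical across
reruns of the same config and seed except for its timestamp.

Individual stages run as `samsurf cluster|density|binding|rdf|angles|msd|paths
<config>`; `samsurf build` prints surface properties and `samsurf simulate`
writes the raw trajectory (multi-frame XYZ with `time_ps=… box=…` comment
metadata, or multi-MODEL PDB with CRYST1).

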