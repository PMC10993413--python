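# Methods

## Scope and model system

`samsurf` analyzes trajectories of monovalent cations over a
ligand-functionalized self-assembled monolayer (SAM), the geometry used to
model multimodal chromatography resin surfaces: a periodic slab box
(periodic x,y; open z) whose floor is a lattice of alkyl-thiol strand
anchors, a fraction of which carry a singly negatively charged multimodal
ligand presenting a carboxylate and a phenyl group on a tether, the rest
terminating in hydroxyls. The reference surface is a 24 × 22 offset
lattice in a 110 × 104 Å box — 528 strands, 132 ligands, hence 132
neutralizing monovalent cations and a realized ligand density of
1.15 /nm² (the builder reports the realized density rather than forcing a
nominal 1 /nm²; 132 ligands on 114.4 nm² cannot give exactly 1 /nm²).

The lattice is hexagonal-like: rows offset by half a column spacing, with
the spacings scaled independently in x and y so the lattice tiles the
periodic box exactly. Exact 60° angles are sacrificed for periodic
consistency.

Because no trajectory data are deposited for such systems, the package
ships a Brownian-dynamics generator with fully known parameters as its
data source; every analysis is validated against truths planted by that
generator.

## Brownian-dynamics generator

Particles (ions, and optionally mobile carboxylate/phenyl head-group
sites) follow the overdamped Langevin equation integrated by
Euler–Maruyama:

    r ← r − (D / k_B T) ∇U dt + sqrt(2 D dt) η,   η ~ N(0, 1) per coordinate

with x,y wrapped into the box and z confined by harmonic walls at the box
faces (smooth forces; overdamped dynamics has no velocity to reflect).
Units: Å, ps, K, kJ/mol; D in Å²/ps, where 0.1 Å²/ps ≡ 1.0 × 10⁻⁹ m²/s.

Interactions are deliberately simple and smooth:

- Gaussian pair wells U(r) = −ε exp(−r²/2w²) for ion–carboxylate
  attraction (and optional phenyl–phenyl attraction), positive-prefactor
  Gaussians for ion–ion and carboxylate–carboxylate repulsion;
- a z-only Gaussian surface well mimicking the surface affinity of large
  ions;
- a z-only smoothed square well U(z) = −ε/(1 + exp((z − z_edge)/a)) whose
  bound/unbound partition has a closed form, used for free-energy
  validation;
- an optional harmonic z spring (equipartition diagnostics);
- harmonic tethers holding head-group sites to their rest positions
  (flexible: k = 0.5 kJ/mol/Å², carboxylate rest height 12 Å, phenyl 8 Å;
  rigid: k = 50, carboxylate 14 Å above the phenyl at 5 Å, mirroring an
  attachment that points the carboxylate into the solvent). Tether
  displacements use the minimum image so sites near a periodic boundary
  never see a box-length stretch.

Each carboxylate is one mobile oxygen interaction site plus a carbon site
rigidly offset 1.25 Å below it (a C–O bond length), giving the ion–O–C
angle analysis a defined geometry without internal carboxylate dynamics.

There is no explicit water, no electrostatics and no fitted force field:
well depths are free knobs, not parameterizations of specific cations.
Raising the ion–carboxylate depth stands in for moving from large, weakly
coordinating cations toward small, tightly binding ones; trends along
that ladder, not absolute numbers, are the meaningful output.

Numerical safeguards: runs are bit-for-bit reproducible for a fixed seed;
a per-step guard aborts when any deterministic drift from the
feature-scale (Gaussian/step) forces exceeds half the narrowest active
well width — the signature of a timestep too coarse to resolve the well.
Harmonic terms (walls, springs, tethers) are instead validated once by
the Euler–Maruyama relaxation criterion D·k·dt/k_BT ≤ 1/2; a harmonic
force is self-limiting and would otherwise trip a feature-scale guard
spuriously on rare deep wall penetrations in large ensembles. Ions
initialize uniformly, or from the exact Boltzmann density of the z-only
potential via inverse-CDF sampling when equilibrium initial conditions
are wanted.

## Cluster statistics

Molecules are linked when any pair of selected atoms (phenyl carbons at
4 Å; carboxylate carbon or oxygen at 5 Å) lies strictly closer than the
cutoff under the minimum image in x,y; clusters are connected components
(single linkage). Distances exactly at the cutoff do not link — the
convention had to be fixed one way and exact ties are measure-zero.
Neighbor search uses a k-d tree with a toroidal box (the open z axis gets
an oversized period that never wraps), union–find for components, and a
brute-force BFS implementation kept as an independent oracle.

Singletons count as clusters of size 1 by default: sparse systems have
mean sizes barely above 1, which is only expressible with singletons
included. A `min_size` filter (applied before normalization) is exposed
for the alternative convention. Clusters are pooled across all frames of
the analysis window, each frame an independent observation. Mixed
ion–carboxylate clustering treats each ion as a single-atom molecule and
reports per-cluster (ion, moiety) compositions.

## Density profiles and binding free energy

z-density profiles are per-bin counts averaged over frames divided by
(area × bin width), in atoms/Å³, with z measured from the strand-anchor
plane. Default bin width 0.25 Å, fine enough to resolve sub-Å region
boundaries. Every profile satisfies area × Σρ Δz = mean selected-atom
count (bins must span the soft-wall overshoot to catch every sample).

The bound layer extends to z_int, where the ligand density "reaches
zero"; numerically, the upper edge of the last bin above
epsilon_frac × max(ρ) scanning outward from the peak (default 10⁻³ —
exact zero is measure-zero for finite sampling). With p_bound the
fraction of ion observations below z_int (pooled across frames;
equivalently the density-integral ratio up to z_max):

    ΔG_binding = −k_B T ln(p_bound / p_unbound)

reported in kJ/mol and in k_BT units (k_B = 0.0083144626 kJ/mol/K;
k_BT = 2.48 kJ/mol near 298 K). Degenerate occupancies (p ∈ {0, 1}) are
flagged unbounded instead of silently returning ±∞.

Region partitioning offers the two conventions used for such profiles:
inflections of the (Gaussian-smoothed, σ = 1 bin — shifts inflections by
at most about a bin) carboxylate density bracketing its maximum, or the
support method returning the extent of bins above threshold ("fully
encompass" the moiety density). Smoothing is documented because it is the
one numerical choice that moves the reported boundaries.

## Ordering measures

Ion–ion pair distributions within a z slab default to a raw pair density
in atoms/Å³ (counts per full spherical-shell volume per ion per frame),
the axis convention of surface-layer pair-distribution plots; a
dimensionless g(r) is also available, normalized by the mean slab density
with shell volumes truncated analytically by the slab planes
(spherical-cap formula — deterministic, no Monte Carlo), so an ideal gas
gives g = 1.

The angular measure is the angle at a carboxylate oxygen between O→ion
and O→C over all ion–oxygen pairs within a contact cutoff (default
3.2 Å, a typical first-shell ion–oxygen distance; the first minimum of
the ion–O pair distribution is the documented alternative). The raw θ
density is reported; a sin θ-corrected variant is optional. An
alternative reading of this observable — angles between the carboxylate
group axis and the alkyl chain — is deliberately not implemented.

## Bound-layer dynamics

"Diffusivity in the bound layer" requires a residence convention, chosen
as: maximal runs of consecutive frames with z inside the layer, runs
shorter than `min_duration` (default 10 frames) discarded as transients.
The MSD is time-origin averaged over PBC-unwrapped x,y displacements with
origins and lags confined within single segments (computed per segment by
the FFT autocorrelation decomposition, verified against the direct double
loop), so exits and re-entries never contaminate displacements. Lateral
(2D) MSD is the default because bound-layer motion is slab-confined; the
Einstein fit D = slope/(2·dim) runs over an interior lag window (default
10–50% of the maximum lag) to avoid the short-time regime and the
poorly-sampled tail. Negative fitted slopes clamp to D = 0 with a flag.
D is reported in Å²/ps and ×10⁻⁹ m²/s (exact factor 10); normalization
by a bulk D uses a potential-free companion run at identical parameters.

## Validation studies (samsurf.studies)

The reference studies freeze the conditions used by the test suite and
`scripts/acceptance.py`:

- **Two-level binding** — smoothed square well, depth 2 k_BT, bound
  fraction 0.2 of a 25 Å box, 10⁵ ions initialized from the exact
  equilibrium density, 240,000 pooled samples. Smoothing 0.10 Å and wall
  stiffness 100 kJ/mol/Å² were chosen (by quadrature of the realized
  potential, independent of any BD output) so the realized partition
  ratio matches the ideal closed form p_bound = f e²/(f e² + 1 − f) to
  ~0.003 kJ/mol; the recovery tolerance is 0.1 kJ/mol.
- **Free diffusion** — 500 force-free ions × 2000 frames at
  D = 0.1 Å²/ps; the lateral-MSD fit must return D within 5%.
- **Ion-specificity trend** — well-depth ladder 0/8/16/24 kJ/mol on a
  64-ligand surface, 2 ns per rung at one seed, all else fixed: mean
  ion–carboxylate cluster size must increase strictly and bound-layer D
  decrease strictly (Spearman ρ = ±1). An earlier design with a competing
  ion–surface well trapped ions kinetically at the surface on these
  timescales and was replaced; the run length (2 ns) is what this system
  needs for ions to find and exchange between carboxylates.
- **Boltzmann consistency** — 5000 independent ions equilibrated 300 ps
  into a Gaussian surface well; the final-frame z histogram is a true
  multinomial draw tested by chi-square against the analytic Boltzmann
  weights.
- **Conservation** — the density-profile counting identity to 10⁻⁹ atoms
  on generated fixtures.

## What the synthetic data does and does not show

The generator emulates the geometry (slab periodicity, anchored ligand
lattice, tethered head groups, neutralizing ion population) and the
qualitative physics (ion–carboxylate association, surface affinity,
binding-slowed diffusion) of the all-atom systems it stands in for. It
omits water structure, electrostatic screening, hydrogen-bond specificity
and cation–π effects. Passing tests therefore demonstrate that the
analysis machinery — clustering, profiles, free energies, ordering,
diffusivities — recovers known truths from trajectories of the right
shape; they do not certify the absolute cluster sizes, region boundaries
or per-cation free energies of any real chromatographic surface.

## Known limitations

- Euler–Maruyama is first-order; stationary densities carry O(dt) bias.
  The studies keep drift per step well below the noise amplitude, and the
  binding study initializes at equilibrium so no burn-in bias enters.
- The pair-distribution slab correction assumes flat slab boundaries and
  uniform density across the slab when normalizing.
- Trajectory I/O covers multi-frame XYZ and PDB only; binary formats
  would slot in behind the same `Trajectory` contract.
- 2D in-plane density maps are not implemented.
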