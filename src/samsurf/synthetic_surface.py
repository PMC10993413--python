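"""Idealized SAM surface model and overdamped Langevin (Brownian) dynamics.

The surface is a hexagonal-like lattice of alkyl-thiol strand anchors in
a periodic slab box, a configurable fraction of which carry a singly
negatively charged multimodal ligand (carboxylate + phenyl pseudo-sites
on a tether), the rest terminating in hydroxyls.  Ion trajectories are
generated by Euler-Maruyama integration of the overdamped Langevin
equation

    r <- r - (D / k_B T) * grad(U) * dt + sqrt(2 D dt) * eta

with smooth Gaussian pair wells, harmonic tethers, and harmonic walls at
the box faces in z.  Every statistic downstream (cluster sizes, density
profiles, binding free energy, pair/angle ordering, diffusivities) then
has a planted, analytically known truth: the input diffusivity, the
Boltzmann weight of any z-only potential, and planted cluster labels.

Interaction strengths are free knobs, not fits: raising the
ion-carboxylate well depth mimics moving down the cation series toward
small, tightly binding ions, and a separate ion-surface well mimics the
surface affinity of large ions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from samsurf.constants import KB_KJ_PER_MOL_K
from samsurf.traj_io import BoxSpec, Frame, Topology, Trajectory

#: Tether stiffness (kJ/mol/A^2) at or above which a ligand counts as rigid.
RIGID_STIFFNESS_FLOOR = 10.0

#: Rigid offset (A) of the carboxylate carbon below its oxygen site,
#: comparable to a C-O bond length.
CARB_CO_OFFSET = 1.25

_TETHER_DEFAULTS = {
    # mode: (stiffness kJ/mol/A^2, carboxylate height A, phenyl height A)
    "flexible": (0.5, 12.0, 8.0),
    "rigid": (50.0, 14.0, 5.0),
}


@dataclass
class LigandSite:
    anchor_index: int
    carboxylate_position: np.ndarray  # rest position, 3-vector A
    phenyl_position: np.ndarray  # rest position, 3-vector A
    tether_mode: str  # "flexible" | "rigid"
    tether_stiffness: float  # kJ/(mol A^2)
    tether_anchor_height: float  # A


@dataclass
class SurfaceModel:
    """Strand-anchor lattice with per-site roles and ligand pseudo-sites."""

    box: BoxSpec
    anchor_sites: np.ndarray  # (n_sites, 2) in A
    site_roles: np.ndarray  # "hydroxyl" | "ligand" per site
    ligand_sites: list[LigandSite]
    charge_per_ligand: int = -1

    def __post_init__(self) -> None:
        n_lig = int(np.sum(self.site_roles == "ligand"))
        if n_lig != len(self.ligand_sites):
            raise ValueError(
                f"{n_lig} ligand site roles but {len(self.ligand_sites)} ligand records"
            )
        for ls in self.ligand_sites:
            if ls.tether_mode == "rigid" and ls.tether_stiffness < RIGID_STIFFNESS_FLOOR:
                raise ValueError(
                    f"rigid ligand stiffness {ls.tether_stiffness} below floor "
                    f"{RIGID_STIFFNESS_FLOOR} kJ/mol/A^2"
                )

    @property
    def n_sites(self) -> int:
        return len(self.anchor_sites)

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_sites)

    @property
    def realized_ligand_density_per_nm2(self) -> float:
        """Ligands per nm^2 of surface, as actually built."""
        return self.n_ligands / (self.box.area_xy / 100.0)

    def neutralizing_cation_count(self) -> int:
        """Monovalent cations required for electroneutrality."""
        return self.n_ligands * abs(self.charge_per_ligand)


def build_surface_model(
    box_x_nm: float,
    box_y_nm: float,
    box_z_nm: float = 10.0,
    n_cols: int = 24,
    n_rows: int = 22,
    ligand_fraction: float = 0.25,
    tether_mode: str = "flexible",
) -> SurfaceModel:
    """Offset (approximately hexagonal) anchor lattice filling the box.

    Rows are offset by half a column spacing; the lattice is scaled
    independently in x and y to tile the periodic box exactly, so angles
    are only approximately 60 degrees.  Every k-th site bears a ligand so
    that the ligand count equals round(ligand_fraction * n_sites), spread
    evenly across the surface.  Box lengths are given in nm and stored
    internally in A.
    """
    if min(box_x_nm, box_y_nm, box_z_nm) <= 0:
        raise ValueError("box lengths must be positive")
    if n_cols < 1 or n_rows < 1:
        raise ValueError("n_cols and n_rows must be >= 1")
    if not 0.0 <= ligand_fraction <= 1.0:
        raise ValueError(f"ligand_fraction must be in [0, 1], got {ligand_fraction}")
    if tether_mode not in _TETHER_DEFAULTS:
        raise ValueError(f"tether_mode must be one of {sorted(_TETHER_DEFAULTS)}")
    box = BoxSpec(10.0 * box_x_nm, 10.0 * box_y_nm, 10.0 * box_z_nm)
    ax = box.lx / n_cols
    ay = box.ly / n_rows
    sites = np.empty((n_cols * n_rows, 2))
    k = 0
    for j in range(n_rows):
        for i in range(n_cols):
            sites[k, 0] = (i + 0.5 * (j % 2)) * ax % box.lx
            sites[k, 1] = j * ay
            k += 1
    n_sites = len(sites)
    n_lig = int(round(ligand_fraction * n_sites))
    lig_idx = np.floor(np.arange(n_lig) * n_sites / max(n_lig, 1)).astype(int)
    roles = np.array(["hydroxyl"] * n_sites, dtype=object)
    roles[lig_idx] = "ligand"
    stiffness, carb_h, phen_h = _TETHER_DEFAULTS[tether_mode]
    ligands = [
        LigandSite(
            anchor_index=int(i),
            carboxylate_position=np.array([sites[i, 0], sites[i, 1], carb_h]),
            phenyl_position=np.array([sites[i, 0], sites[i, 1], phen_h]),
            tether_mode=tether_mode,
            tether_stiffness=stiffness,
            tether_anchor_height=carb_h,
        )
        for i in lig_idx
    ]
    return SurfaceModel(box=box, anchor_sites=sites, site_roles=roles, ligand_sites=ligands)


@dataclass(frozen=True)
class PotentialSpec:
    """Smooth interaction model: Gaussian wells, harmonic tethers and walls.

    Pair wells have the form U(r) = -eps * exp(-r^2 / (2 w^2)) (attraction;
    positive prefactor for repulsion).  The ion-surface well and the
    optional smoothed step well act on z only; the step well

        U(z) = -depth / (1 + exp((z - edge) / smoothing))

    approximates a two-level (square-well) system with an analytically
    known bound/unbound partition, used for free-energy validation.  An
    optional harmonic z spring supports equipartition diagnostics.  All
    energies in kJ/mol, lengths in A.
    """

    ion_carboxylate_well_depth: float = 0.0
    ion_carboxylate_well_width: float = 2.0
    ion_surface_well_depth: float = 0.0
    ion_surface_well_width: float = 2.0
    ion_ion_repulsion_strength: float = 0.0
    ion_ion_repulsion_range: float = 2.0
    carboxylate_repulsion_strength: float = 0.0
    carboxylate_repulsion_range: float = 2.0
    phenyl_phenyl_well_depth: float = 0.0
    phenyl_phenyl_well_width: float = 2.0
    wall_stiffness: float = 10.0
    step_well_depth: float = 0.0
    step_well_edge: float = 0.0
    step_well_smoothing: float = 0.5
    ion_z_spring_k: float = 0.0
    ion_z_spring_z0: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "ion_carboxylate_well_width",
            "ion_surface_well_width",
            "ion_ion_repulsion_range",
            "carboxylate_repulsion_range",
            "phenyl_phenyl_well_width",
            "step_well_smoothing",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("ion_carboxylate_well_depth", "ion_surface_well_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def min_well_width(self) -> float:
        widths = []
        if self.ion_carboxylate_well_depth > 0:
            widths.append(self.ion_carboxylate_well_width)
        if self.ion_surface_well_depth > 0:
            widths.append(self.ion_surface_well_width)
        if self.ion_ion_repulsion_strength != 0:
            widths.append(self.ion_ion_repulsion_range)
        if self.carboxylate_repulsion_strength != 0:
            widths.append(self.carboxylate_repulsion_range)
        if self.phenyl_phenyl_well_depth > 0:
            widths.append(self.phenyl_phenyl_well_width)
        if self.step_well_depth != 0:
            widths.append(self.step_well_smoothing)
        return min(widths) if widths else math.inf

    # -- z-only external potential on ions (surface well + step well + spring
    #    + walls); analytic reference for Boltzmann/binding validation

    def ion_z_potential(self, z: np.ndarray, box: BoxSpec) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        u = np.zeros_like(z)
        if self.ion_surface_well_depth > 0:
            w = self.ion_surface_well_width
            u -= self.ion_surface_well_depth * np.exp(-(z**2) / (2 * w**2))
        if self.step_well_depth != 0:
            a = self.step_well_smoothing
            u -= self.step_well_depth / (1.0 + np.exp((z - self.step_well_edge) / a))
        if self.ion_z_spring_k > 0:
            u += 0.5 * self.ion_z_spring_k * (z - self.ion_z_spring_z0) ** 2
        u += 0.5 * self.wall_stiffness * np.where(z < 0, z, 0.0) ** 2
        u += 0.5 * self.wall_stiffness * np.where(z > box.lz, z - box.lz, 0.0) ** 2
        return u

    def _ion_z_force(
        self, z: np.ndarray, box: BoxSpec, include_walls: bool = True
    ) -> np.ndarray:
        f = np.zeros_like(z)
        if self.ion_surface_well_depth > 0:
            w = self.ion_surface_well_width
            f -= (self.ion_surface_well_depth / w**2) * z * np.exp(-(z**2) / (2 * w**2))
        if self.step_well_depth != 0:
            a = self.step_well_smoothing
            s = 1.0 / (1.0 + np.exp((z - self.step_well_edge) / a))
            f -= (self.step_well_depth / a) * s * (1.0 - s)
        if self.ion_z_spring_k > 0:
            f -= self.ion_z_spring_k * (z - self.ion_z_spring_z0)
        if include_walls:
            f += self.wall_z_force(z, box)
        return f

    def wall_z_force(self, z: np.ndarray, box: BoxSpec) -> np.ndarray:
        f = -self.wall_stiffness * np.where(z < 0, z, 0.0)
        f -= self.wall_stiffness * np.where(z > box.lz, z - box.lz, 0.0)
        return f


@dataclass(frozen=True)
class BDParams:
    """Integration and sampling parameters for the Brownian propagator.

    Diffusivities in A^2/ps (0.1 A^2/ps == 1.0e-9 m^2/s), timestep in ps.
    ``ion_init`` is "uniform" or "boltzmann_z" (equilibrium sampling of the
    z-only part of the ion potential; x,y uniform).
    """

    ion_diffusivity_input: float = 0.1
    headgroup_diffusivity_input: float = 0.0
    temperature: float = 300.0
    timestep: float = 0.1
    n_steps: int = 1000
    save_stride: int = 10
    n_ions: int = 132
    rng_seed: int = 0
    ion_species: str = "NA"
    ion_init: str = "uniform"

    def __post_init__(self) -> None:
        if self.ion_diffusivity_input < 0 or self.headgroup_diffusivity_input < 0:
            raise ValueError("diffusivities must be >= 0")
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.n_steps < 1 or self.save_stride < 1:
            raise ValueError("n_steps and save_stride must be >= 1")
        if self.n_ions < 0:
            raise ValueError("n_ions must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.ion_init not in ("uniform", "boltzmann_z"):
            raise ValueError("ion_init must be 'uniform' or 'boltzmann_z'")


def sample_boltzmann_z(
    potential: PotentialSpec, box: BoxSpec, temperature: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw exact samples of z from exp(-U(z)/k_B T) by inverse-CDF on a grid."""
    kT = KB_KJ_PER_MOL_K * temperature
    pad = 5.0 / math.sqrt(max(potential.wall_stiffness, 1e-6) / kT)
    grid = np.linspace(-pad, box.lz + pad, 20001)
    u = potential.ion_z_potential(grid, box)
    w = np.exp(-(u - u.min()) / kT)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)


def _gaussian_pair_force(
    pos_a: np.ndarray, pos_b: np.ndarray, prefactor: float, width: float, box: BoxSpec,
    exclude_self: bool = False,
) -> np.ndarray:
    """Force on each particle of ``pos_a`` from a Gaussian pair potential
    U = prefactor * exp(-r^2/2w^2) with all of ``pos_b`` (minimum image).

    ``prefactor`` < 0 is attraction.  Returns (len(pos_a), 3).
    """
    d = pos_a[:, None, :] - pos_b[None, :, :]
    for axis, (length, per) in enumerate(zip(box.lengths, box.periodic)):
        if per:
            d[..., axis] -= length * np.round(d[..., axis] / length)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    g = (prefactor / width**2) * np.exp(-r2 / (2 * width**2))
    if exclude_self:
        np.fill_diagonal(g, 0.0)
    # F_a = -dU/da = +(prefactor/w^2) e^{-r^2/2w^2} (a-b)
    return np.einsum("ij,ijk->ik", g, d)


def bd_simulate(
    surface: SurfaceModel, potential: PotentialSpec, params: BDParams
) -> Trajectory:
    """Propagate ions (and mobile ligand pseudo-sites) by Euler-Maruyama.

    The returned trajectory contains the ions followed by one carboxylate
    and one phenyl pseudo-atom per ligand (static when
    ``headgroup_diffusivity_input`` is 0); x,y are wrapped into the box
    and z is confined by the harmonic walls.  Output is reproducible
    bit-for-bit for a fixed ``rng_seed``.

    A displacement guard aborts with a diagnostic if any deterministic
    per-step drift exceeds half the narrowest active well width — the
    signature of a timestep too large for the chosen potential.
    """
    box = surface.box
    kT = KB_KJ_PER_MOL_K * params.temperature
    dt = params.timestep
    rng = np.random.default_rng(params.rng_seed)
    n_ions = params.n_ions
    n_lig = surface.n_ligands

    # per ligand: a mobile carboxylate oxygen (the interaction site), a
    # carboxylate carbon slaved CARB_CO_OFFSET below it, and a phenyl site
    roles = (
        ["ion"] * n_ions
        + ["carboxylate_O"] * n_lig
        + ["carboxylate_C"] * n_lig
        + ["phenyl_C"] * n_lig
    )
    species = (
        [params.ion_species] * n_ions + ["CAO"] * n_lig + ["CAC"] * n_lig + ["PHE"] * n_lig
    )
    mol_id = list(range(n_ions)) + list(range(n_ions, n_ions + n_lig)) * 3
    topo = Topology(
        roles=np.array(roles, dtype=object),
        molecule_id=np.array(mol_id, dtype=int),
        species=np.array(species, dtype=object),
    )

    carb_rest = np.array([ls.carboxylate_position for ls in surface.ligand_sites]).reshape(n_lig, 3)
    phen_rest = np.array([ls.phenyl_position for ls in surface.ligand_sites]).reshape(n_lig, 3)
    tether_k = np.array([ls.tether_stiffness for ls in surface.ligand_sites]).reshape(n_lig, 1)

    ions = np.empty((n_ions, 3))
    ions[:, 0] = rng.random(n_ions) * box.lx
    ions[:, 1] = rng.random(n_ions) * box.ly
    if params.ion_init == "boltzmann_z":
        ions[:, 2] = sample_boltzmann_z(potential, box, params.temperature, n_ions, rng)
    else:
        ions[:, 2] = 1.0 + rng.random(n_ions) * (box.lz - 2.0)
    carb = carb_rest.copy()
    phen = phen_rest.copy()

    D_ion = params.ion_diffusivity_input
    D_head = params.headgroup_diffusivity_input
    mobile_head = D_head > 0 and n_lig > 0
    guard = 0.5 * min(potential.min_well_width(), box.lz)
    sigma_ion = math.sqrt(2.0 * D_ion * dt)
    sigma_head = math.sqrt(2.0 * D_head * dt)

    def forces():
        f_ion = np.zeros((n_ions, 3))
        f_carb = np.zeros((n_lig, 3))
        f_phen = np.zeros((n_lig, 3))
        if n_ions:
            f_ion[:, 2] += potential._ion_z_force(ions[:, 2], box, include_walls=False)
            if potential.ion_carboxylate_well_depth > 0 and n_lig:
                f = _gaussian_pair_force(
                    ions, carb, -potential.ion_carboxylate_well_depth,
                    potential.ion_carboxylate_well_width, box,
                )
                f_ion += f
                f_carb += _gaussian_pair_force(
                    carb, ions, -potential.ion_carboxylate_well_depth,
                    potential.ion_carboxylate_well_width, box,
                )
            if potential.ion_ion_repulsion_strength != 0 and n_ions > 1:
                f_ion += _gaussian_pair_force(
                    ions, ions, potential.ion_ion_repulsion_strength,
                    potential.ion_ion_repulsion_range, box, exclude_self=True,
                )
        if n_lig:
            if potential.carboxylate_repulsion_strength != 0 and n_lig > 1:
                f_carb += _gaussian_pair_force(
                    carb, carb, potential.carboxylate_repulsion_strength,
                    potential.carboxylate_repulsion_range, box, exclude_self=True,
                )
            if potential.phenyl_phenyl_well_depth > 0 and n_lig > 1:
                f_phen += _gaussian_pair_force(
                    phen, phen, -potential.phenyl_phenyl_well_depth,
                    potential.phenyl_phenyl_well_width, box, exclude_self=True,
                )
            # tether displacement by minimum image: sites near a periodic
            # boundary must not see a box-length stretch after wrapping
            for f_head, p, rest in ((f_carb, carb, carb_rest), (f_phen, phen, phen_rest)):
                d = p - rest
                d[:, 0] -= box.lx * np.round(d[:, 0] / box.lx)
                d[:, 1] -= box.ly * np.round(d[:, 1] / box.ly)
                f_head -= tether_k * d
        return f_ion, f_carb, f_phen

    def wrap_xy(p):
        p[:, 0] %= box.lx
        p[:, 1] %= box.ly

    co_offset = np.array([0.0, 0.0, -CARB_CO_OFFSET])

    def snapshot(t: float) -> Frame:
        return Frame(
            time=t,
            positions=np.concatenate([ions, carb, carb + co_offset, phen]),
            box=box,
        )

    frames = [snapshot(0.0)]
    any_force = (
        potential.ion_carboxylate_well_depth > 0
        or potential.ion_surface_well_depth > 0
        or potential.ion_ion_repulsion_strength != 0
        or potential.carboxylate_repulsion_strength != 0
        or potential.phenyl_phenyl_well_depth > 0
        or potential.step_well_depth != 0
        or potential.ion_z_spring_k > 0
    )
    # harmonic terms (walls, z spring, tethers) are excluded from the
    # per-step guard; their Euler-Maruyama stability is the once-off
    # condition theta*dt = D*k*dt/kT <= 1/2
    for k, D in ((potential.wall_stiffness, max(D_ion, D_head)),
                 (potential.ion_z_spring_k, D_ion),
                 (float(tether_k.max()) if n_lig else 0.0, D_head)):
        if k > 0 and D > 0 and D * k * dt / kT > 0.5:
            raise RuntimeError(
                f"timestep instability: harmonic stiffness {k} kJ/mol/A^2 gives "
                f"relaxation fraction D*k*dt/kT = {D * k * dt / kT:.2f} > 0.5 per "
                "step; reduce the timestep"
            )
    for step in range(1, params.n_steps + 1):
        if any_force or mobile_head:
            f_ion, f_carb, f_phen = forces()
            drift_ion = (D_ion / kT) * f_ion * dt
            max_drift = np.abs(drift_ion).max() if n_ions else 0.0
            if mobile_head:
                drift_carb = (D_head / kT) * f_carb * dt
                drift_phen = (D_head / kT) * f_phen * dt
                max_drift = max(max_drift, np.abs(drift_carb).max(), np.abs(drift_phen).max())
            if max_drift > guard:
                raise RuntimeError(
                    f"timestep instability at step {step}: drift {max_drift:.3g} A "
                    f"exceeds the stability guard {guard:.3g} A "
                    "(half the narrowest active well width); reduce the timestep"
                )
            if n_ions:
                ions += drift_ion
            if mobile_head:
                carb += drift_carb
                phen += drift_phen
        if potential.wall_stiffness > 0:
            if n_ions:
                ions[:, 2] += (D_ion / kT) * potential.wall_z_force(ions[:, 2], box) * dt
            if mobile_head:
                carb[:, 2] += (D_head / kT) * potential.wall_z_force(carb[:, 2], box) * dt
                phen[:, 2] += (D_head / kT) * potential.wall_z_force(phen[:, 2], box) * dt
        if D_ion > 0 and n_ions:
            ions += sigma_ion * rng.standard_normal((n_ions, 3))
        if mobile_head:
            carb += sigma_head * rng.standard_normal((n_lig, 3))
            phen += sigma_head * rng.standard_normal((n_lig, 3))
        wrap_xy(ions)
        if mobile_head:
            wrap_xy(carb)
            wrap_xy(phen)
        if step % params.save_stride == 0:
            frames.append(snapshot(step * dt))
    return Trajectory(topology=topo, frames=frames)


@dataclass
class PlantedPartition:
    """Molecule positions with known cluster labels for recovery tests."""

    positions: list[np.ndarray]  # per-molecule (n_atoms, 3) arrays, A
    true_labels: np.ndarray  # per-molecule cluster id
    box: BoxSpec
    cutoff: float  # the linkage cutoff the construction guarantees

    def to_frame_topology(self, role: str = "phenyl_C") -> tuple[Frame, Topology]:
        """Materialize as a Frame + Topology consumable by the clustering module."""
        pos = np.concatenate(self.positions)
        mol_id = np.concatenate(
            [np.full(len(p), m) for m, p in enumerate(self.positions)]
        )
        topo = Topology(
            roles=np.array([role] * len(pos), dtype=object),
            molecule_id=mol_id.astype(int),
            species=np.array(["X"] * len(pos), dtype=object),
        )
        return Frame(time=0.0, positions=pos, box=self.box), topo


def plant_clusters(
    cluster_sizes: list[int],
    intra_spread: float,
    inter_separation: float,
    box: BoxSpec,
    seed: int = 0,
    cutoff: float = 4.0,
    atoms_per_molecule: int = 1,
) -> PlantedPartition:
    """Place molecules so single-linkage clustering at ``cutoff`` is unambiguous.

    Molecules of one cluster form a chain with nearest-atom spacing
    ``intra_spread`` (< cutoff); cluster anchors sit on a grid whose gaps
    exceed ``inter_separation`` (> cutoff).  Ground-truth labels are
    returned alongside the positions.
    """
    if not 0 < intra_spread < cutoff:
        raise ValueError(f"need 0 < intra_spread < cutoff, got {intra_spread} vs {cutoff}")
    if inter_separation <= cutoff:
        raise ValueError(f"inter_separation {inter_separation} must exceed cutoff {cutoff}")
    if any(s < 1 for s in cluster_sizes):
        raise ValueError("cluster sizes must be >= 1")
    rng = np.random.default_rng(seed)
    n_clusters = len(cluster_sizes)
    chain_extent = (max(cluster_sizes) - 1) * intra_spread
    cols = int(math.ceil(math.sqrt(n_clusters)))
    rows = int(math.ceil(n_clusters / cols))
    cell_x = box.lx / cols
    cell_y = box.ly / rows
    if cell_x < chain_extent + inter_separation or cell_y < inter_separation:
        raise ValueError(
            f"infeasible geometry: grid cell {cell_x:.1f} x {cell_y:.1f} A cannot hold "
            f"a chain of extent {chain_extent:.1f} A separated by {inter_separation:.1f} A"
        )
    jitter = min(0.05 * intra_spread, 0.1 * (inter_separation - cutoff))
    positions: list[np.ndarray] = []
    labels: list[int] = []
    z0 = box.lz / 2.0
    for c, size in enumerate(cluster_sizes):
        ox = (c % cols) * cell_x + 1.0
        oy = (c // cols) * cell_y + 1.0
        for m in range(size):
            base = np.array([ox + m * intra_spread, oy, z0])
            atoms = np.tile(base, (atoms_per_molecule, 1))
            atoms[:, 2] += 0.02 * np.arange(atoms_per_molecule)  # distinct coordinates
            atoms += jitter * rng.uniform(-1, 1, atoms.shape)
            positions.append(atoms)
            labels.append(c)
    return PlantedPartition(
        positions=positions,
        true_labels=np.array(labels, dtype=int),
        box=box,
        cutoff=cutoff,
    )
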