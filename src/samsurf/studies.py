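"""Planted-truth validation studies run on the synthetic generator.

Each function freezes one study design — system size, potential, sampling
length — and returns both the planted truth and the value recovered by
the analysis pipeline, so recovery can be asserted end to end.  All
randomness derives from a single seed argument.

The study designs are the package's reference conditions:

* binding: ions equilibrated in a smoothed two-level (square-well) z
  potential of depth 2 k_B T whose bound region is 20% of the box, where
  the bound/unbound partition has a closed form;
* diffusion: potential-free ions whose MSD slope must return the input
  diffusivity;
* ion-specificity trend: a ladder of ion-carboxylate well depths standing
  in for the small->large cation series, which must order mean
  ion-carboxylate cluster size upward and bound-layer diffusivity
  downward;
* Boltzmann consistency: the z histogram of ions in a known z potential
  against exp(-U/k_B T).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from samsurf.clustering import cluster_size_distribution, ion_moiety_clusters
from samsurf.constants import KB_KJ_PER_MOL_K
from samsurf.density_binding import binding_stats, z_density_profile
from samsurf.dynamics import fit_diffusivity, lateral_msd, layer_resident_segments
from samsurf.synthetic_surface import (
    BDParams,
    PotentialSpec,
    bd_simulate,
    build_surface_model,
)
from samsurf.traj_io import analysis_window, select


def _subseed(seed: int, offset: int) -> int:
    return int((seed * 1_000_003 + offset) % (2**31 - 1))


def two_level_binding_study(seed: int = 1) -> dict:
    """Recover the binding free energy of a two-level Boltzmann system by BD.

    A smoothed square well of depth 2 k_B T occupies the lowest 20% of a
    25 A box.  Ions are initialized from the exact equilibrium density and
    propagated by Brownian dynamics (which must preserve it); the pooled
    z samples yield dG through the bound/unbound probability ratio.  The
    ideal two-level closed form is p_bound = f e^2 / (f e^2 + 1 - f) with
    f = 0.2.
    """
    T = 300.0
    kT = KB_KJ_PER_MOL_K * T
    lz = 25.0
    edge = 0.2 * lz
    # smoothing width and wall stiffness realize the ideal square well:
    # at 0.10 A / 100 kJ/mol/A^2 the smoothed-edge and wall-penetration
    # contributions to the partition ratio cancel to ~0.003 kJ/mol
    pot = PotentialSpec(
        step_well_depth=2.0 * kT,
        step_well_edge=edge,
        step_well_smoothing=0.10,
        wall_stiffness=100.0,
    )
    surf = build_surface_model(3.0, 3.0, lz / 10.0, 2, 2, 0.0)
    params = BDParams(
        ion_diffusivity_input=0.1,
        timestep=0.02,
        n_steps=30,
        save_stride=10,
        n_ions=100_000,
        rng_seed=_subseed(seed, 4),
        ion_init="boltzmann_z",
    )
    traj = bd_simulate(surf, pot, params)
    z = traj.positions_of(select(traj.topology, role="ion"))[:, :, 2].ravel()
    bs = binding_stats(ion_z_samples=z, z_int=edge, z_max=lz, temperature=T)

    f = 0.2
    p_closed = f * math.e**2 / (f * math.e**2 + (1.0 - f))
    dg_closed = -kT * math.log(p_closed / (1.0 - p_closed))
    # partition-function ratio of the actual smooth potential (quadrature)
    grid = np.linspace(-2.0, lz + 2.0, 200_001)
    w = np.exp(-pot.ion_z_potential(grid, surf.box) / kT)
    p_quad = float(np.trapezoid(w[grid < edge], grid[grid < edge]) / np.trapezoid(w, grid))
    dg_quad = -kT * math.log(p_quad / (1.0 - p_quad))
    return {
        "delta_G_bd": bs.delta_G,
        "delta_G_closed_form": dg_closed,
        "delta_G_quadrature": dg_quad,
        "abs_error_kJ_mol": abs(bs.delta_G - dg_closed),
        "p_bound": bs.p_bound,
        "n_samples": int(z.size),
    }


def free_diffusion_study(seed: int = 1, n_ions: int = 500, n_frames: int = 2000) -> dict:
    """Recover the input diffusivity of force-free ions from the MSD slope.

    D_in = 0.1 A^2/ps (= 1.0e-9 m^2/s); the lateral MSD over all ions must
    fit back to D_in via MSD = 4 D t.
    """
    D_in = 0.1
    surf = build_surface_model(5.0, 5.0, 5.0, 2, 2, 0.0)
    params = BDParams(
        ion_diffusivity_input=D_in,
        timestep=0.1,
        n_steps=n_frames,
        save_stride=1,
        n_ions=n_ions,
        rng_seed=_subseed(seed, 5),
    )
    traj = bd_simulate(surf, PotentialSpec(wall_stiffness=0.0), params)
    ions = select(traj.topology, role="ion")
    segs = layer_resident_segments(traj, ions, -np.inf, np.inf, min_duration=1)
    msd = lateral_msd(traj, segs, max_lag=n_frames // 5)
    res = fit_diffusivity(msd)
    return {
        "D_input_A2_ps": D_in,
        "D_fit_A2_ps": res.D,
        "D_fit_1e9_m2_s": res.D_1e9_m2_s,
        "rel_error_pct": 100.0 * abs(res.D - D_in) / D_in,
        "n_samples": int(n_ions * n_frames),
    }


#: Ion-carboxylate well depths (kJ/mol) standing in for the cation ladder
#: from large, weakly binding to small, tightly binding ions.
HOFMEISTER_DEPTHS = (0.0, 8.0, 16.0, 24.0)


def hofmeister_trend_study(seed: int = 1, depths: tuple = HOFMEISTER_DEPTHS) -> dict:
    """Cluster-size and diffusivity orderings across a well-depth ladder.

    All parameters except the ion-carboxylate well depth are held fixed;
    each rung reuses the same seed.  Increasing depth mimics moving from
    large to small cations and must order mean ion-carboxylate cluster
    size strictly upward and bound-layer lateral diffusivity strictly
    downward (Spearman rho +1 / -1).
    """
    surf = build_surface_model(8.0, 8.0, 2.5, 16, 16, 0.25, "flexible")
    mean_sizes, d_layers = [], []
    for depth in depths:
        pot = PotentialSpec(
            ion_carboxylate_well_depth=depth,
            ion_carboxylate_well_width=2.5,
            ion_ion_repulsion_strength=2.0,
            ion_ion_repulsion_range=2.0,
            carboxylate_repulsion_strength=1.0,
            carboxylate_repulsion_range=2.0,
            wall_stiffness=20.0,
        )
        params = BDParams(
            ion_diffusivity_input=0.1,
            headgroup_diffusivity_input=0.05,
            timestep=0.05,
            n_steps=40_000,
            save_stride=20,
            n_ions=surf.neutralizing_cation_count(),
            rng_seed=_subseed(seed, 6),
        )
        traj = bd_simulate(surf, pot, params)
        w = analysis_window(traj, last_fraction=0.5)
        parts = [ion_moiety_clusters(f, w.topology, 5.0) for f in w.frames]
        mean_sizes.append(cluster_size_distribution(parts).mean_size)
        ions = select(w.topology, role="ion")
        segs = layer_resident_segments(w, ions, 6.0, 18.0, min_duration=20)
        msd = lateral_msd(w, segs, max_lag=150)
        d_layers.append(fit_diffusivity(msd).D)
    rho_size = float(stats.spearmanr(depths, mean_sizes).statistic)
    rho_D = float(stats.spearmanr(depths, d_layers).statistic)
    return {
        "depths_kJ_mol": list(depths),
        "mean_cluster_sizes": mean_sizes,
        "bound_layer_D_A2_ps": d_layers,
        "spearman_cluster_size": rho_size,
        "spearman_diffusivity": rho_D,
    }


def boltzmann_consistency_study(seed: int = 1) -> dict:
    """z histogram of ions in a known z potential against exp(-U/k_B T).

    Ions start uniform and equilibrate into a Gaussian surface well (depth
    2 k_B T); the final frame holds independent ions, so its binned counts
    are a true multinomial draw against the Boltzmann expectation, tested
    by chi-square.
    """
    T = 300.0
    kT = KB_KJ_PER_MOL_K * T
    lz = 12.0
    pot = PotentialSpec(
        ion_surface_well_depth=2.0 * kT,
        ion_surface_well_width=2.0,
        wall_stiffness=20.0,
    )
    surf = build_surface_model(3.0, 3.0, lz / 10.0, 2, 2, 0.0)
    params = BDParams(
        ion_diffusivity_input=0.3,
        timestep=0.1,
        n_steps=3000,
        save_stride=3000,
        n_ions=5000,
        rng_seed=_subseed(seed, 7),
    )
    traj = bd_simulate(surf, pot, params)
    z = traj.frames[-1].positions[select(traj.topology, role="ion"), 2]
    edges = np.linspace(-3.0, lz + 3.0, 37)
    z = np.clip(z, edges[0] + 1e-9, edges[-1] - 1e-9)  # e^-36 tail weight
    counts, _ = np.histogram(z, bins=edges)
    grid = np.linspace(edges[0], edges[-1], 20_001)
    w = np.exp(-pot.ion_z_potential(grid, surf.box) / kT)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(grid))])
    probs = np.diff(np.interp(edges, grid, cdf))
    probs /= probs.sum()
    # fold bins with tiny expectation into neighbours for chi-square validity
    keep = probs * len(z) >= 5
    obs = np.concatenate([counts[keep], [counts[~keep].sum()]]).astype(float)
    exp = np.concatenate([probs[keep], [probs[~keep].sum()]]) * len(z)
    exp *= obs.sum() / exp.sum()
    chi2 = stats.chisquare(obs, exp)
    return {
        "chi2_statistic": float(chi2.statistic),
        "p_value": float(chi2.pvalue),
        "n_ions": len(z),
        "n_bins": int(len(obs)),
    }


def density_conservation_check(seed: int = 1) -> dict:
    """Conservation identity of density profiles on a generated fixture.

    area * sum(rho) * dz must equal the mean selected-atom count per frame
    for every species; z bins span the soft-wall overshoot so no sample is
    lost.
    """
    surf = build_surface_model(4.0, 4.0, 2.0, 6, 6, 0.25)
    params = BDParams(
        ion_diffusivity_input=0.1, timestep=0.1, n_steps=300, save_stride=10,
        n_ions=surf.neutralizing_cation_count(), rng_seed=_subseed(seed, 8),
    )
    traj = bd_simulate(surf, PotentialSpec(wall_stiffness=20.0), params)
    worst = 0.0
    for role in ("ion", "carboxylate_O", "phenyl_C"):
        sel = select(traj.topology, role=role)
        prof = z_density_profile(traj, sel, bin_width=0.25, z_range=(-5.0, traj.box.lz + 5.0))
        worst = max(worst, abs(prof.mean_atom_count() - len(sel)))
    return {"max_abs_count_error": worst}
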