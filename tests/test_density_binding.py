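"""Density profiles, bound-layer edge, region partitioning, binding dG."""

import math

import numpy as np
import pytest
from scipy import stats

from samsurf.constants import KB_KJ_PER_MOL_K
from samsurf.density_binding import (
    DensityProfile,
    binding_stats,
    find_bound_layer_edge,
    partition_regions,
    z_density_profile,
)
from samsurf.traj_io import BoxSpec

from conftest import make_topology, make_trajectory

KT300 = KB_KJ_PER_MOL_K * 300.0


def traj_with_z(z_values, box, n_frames=1):
    """Trajectory of ions at fixed z (one atom per value)."""
    z_values = np.asarray(z_values, dtype=float)
    topo = make_topology(["ion"] * len(z_values))
    pos = np.column_stack([
        np.full(len(z_values), box.lx / 2),
        np.full(len(z_values), box.ly / 2),
        z_values,
    ])
    return make_trajectory([pos] * n_frames, topo, box)


def profile_from_counts(density, bin_width=1.0, area=100.0):
    density = np.asarray(density, dtype=float)
    edges = bin_width * np.arange(len(density) + 1)
    return DensityProfile(bin_edges=edges, density=density, species="x",
                          n_frames=1, area=area)


class TestZDensityProfile:
    def test_point_mass_density(self):
        """10 atoms at z=7 in a 100 A^2 box with 1 A bins: 0.1 atoms/A^3 in
        bin [7,8), zero elsewhere."""
        box = BoxSpec(10.0, 10.0, 10.0)
        traj = traj_with_z([7.0] * 10, box)
        prof = z_density_profile(traj, np.arange(10), bin_width=1.0)
        assert prof.density[7] == pytest.approx(0.1)
        assert np.sum(prof.density) == pytest.approx(0.1)

    def test_conservation_identity(self, rng):
        box = BoxSpec(25.0, 20.0, 30.0)
        z = rng.uniform(0, box.lz, 57)
        traj = traj_with_z(z, box, n_frames=3)
        prof = z_density_profile(traj, np.arange(57), bin_width=0.25)
        assert prof.mean_atom_count() == pytest.approx(57, abs=1e-9)

    def test_uniform_sampling_is_flat(self, rng):
        """1e4 uniform z samples give a flat profile (chi-square, alpha 1e-3)."""
        box = BoxSpec(10.0, 10.0, 20.0)
        z = rng.uniform(0, box.lz, 10_000)
        traj = traj_with_z(z, box)
        prof = z_density_profile(traj, np.arange(z.size), bin_width=1.0)
        counts = prof.density * prof.area * prof.bin_width
        res = stats.chisquare(counts)
        assert res.pvalue > 1e-3

    def test_empty_selection_rejected(self):
        traj = traj_with_z([1.0], BoxSpec(10, 10, 10))
        with pytest.raises(ValueError, match="empty"):
            z_density_profile(traj, np.array([], dtype=int), 1.0)


class TestBoundLayerEdge:
    def test_exact_zero_tail(self):
        prof = profile_from_counts([0, 1, 5, 2, 0, 0, 0, 0])
        assert find_bound_layer_edge(prof, epsilon_frac=1e-3) == pytest.approx(4.0)
        assert find_bound_layer_edge(prof, epsilon_frac=0.3) == pytest.approx(4.0)

    def test_gaussian_tail_analytic(self):
        """For a Gaussian profile the epsilon_frac=1e-3 edge sits at
        mu + sigma*sqrt(2 ln 1000), within one bin width."""
        mu, sigma, bw = 10.0, 2.0, 0.1
        z = np.arange(0, 30, bw) + bw / 2
        prof = profile_from_counts(np.exp(-((z - mu) ** 2) / (2 * sigma**2)), bin_width=bw)
        expected = mu + sigma * math.sqrt(2 * math.log(1000))
        assert find_bound_layer_edge(prof, 1e-3) == pytest.approx(expected, abs=bw)

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            find_bound_layer_edge(profile_from_counts([0, 0, 0]))

    def test_layer_reaching_box_edge_rejected(self):
        with pytest.raises(ValueError, match="box edge"):
            find_bound_layer_edge(profile_from_counts([1, 2, 3, 4, 5]))


class TestPartitionRegions:
    def test_gaussian_inflections_at_mu_pm_sigma(self):
        mu, sigma, bw = 5.0, 1.5, 0.05
        z = np.arange(0, 10, bw) + bw / 2
        prof = profile_from_counts(np.exp(-((z - mu) ** 2) / (2 * sigma**2)), bin_width=bw)
        part = partition_regions(prof, method="inflection")
        assert part.z1 == pytest.approx(mu - sigma, abs=3 * bw)
        assert part.z2 == pytest.approx(mu + sigma, abs=3 * bw)

    def test_top_hat_support(self):
        rho = np.zeros(40)
        rho[12:20] = 1.0
        prof = profile_from_counts(rho, bin_width=0.5)
        part = partition_regions(prof, method="support")
        assert part.z1 == pytest.approx(6.0)
        assert part.z2 == pytest.approx(10.0)

    def test_monotone_profile_advises_support(self):
        prof = profile_from_counts(np.linspace(0.01, 1.0, 50), bin_width=0.2)
        with pytest.raises(ValueError, match="support"):
            partition_regions(prof, method="inflection")

    def test_occupancy_sums_to_one(self, rng):
        mu, sigma, bw = 5.0, 1.5, 0.05
        z = np.arange(0, 10, bw) + bw / 2
        prof = profile_from_counts(np.exp(-((z - mu) ** 2) / (2 * sigma**2)), bin_width=bw)
        ion = profile_from_counts(rng.random(len(z)), bin_width=bw)
        part = partition_regions(prof, method="inflection", occupancy_profile=ion)
        assert sum(part.occupancy) == pytest.approx(1.0, abs=1e-12)


class TestBindingStats:
    def test_uniform_half_box_gives_zero_dG(self, rng):
        z = rng.uniform(0, 20.0, 200_001)
        bs = binding_stats(ion_z_samples=z, z_int=10.0, z_max=20.0, temperature=300.0)
        assert bs.p_bound == pytest.approx(0.5, abs=0.005)
        assert bs.delta_G == pytest.approx(0.0, abs=0.05)

    def test_two_level_closed_form(self, rng):
        """Samples of a two-level Boltzmann system (depth 2 kT over fraction
        f=0.2) give p_bound = f e^2/(f e^2 + 1 - f) within binomial error."""
        f, beta_eps, n = 0.2, 2.0, 400_000
        z_max = 25.0
        p_true = f * math.exp(beta_eps) / (f * math.exp(beta_eps) + 1 - f)
        bound = rng.random(n) < p_true
        z = np.where(
            bound,
            rng.uniform(0, f * z_max, n),
            rng.uniform(f * z_max, z_max, n),
        )
        bs = binding_stats(ion_z_samples=z, z_int=f * z_max, z_max=z_max, temperature=300.0)
        dg_true = -KT300 * math.log(p_true / (1 - p_true))
        sd = KT300 * (1 / p_true + 1 / (1 - p_true)) * math.sqrt(p_true * (1 - p_true) / n)
        assert bs.delta_G == pytest.approx(dg_true, abs=5 * sd)

    def test_degenerate_occupancy_flagged(self):
        bs = binding_stats(
            ion_z_samples=np.full(100, 2.0), z_int=5.0, z_max=20.0, temperature=300.0
        )
        assert bs.unbounded_flag and bs.p_bound == 1.0 and bs.delta_G == -math.inf

    def test_antisymmetry_under_label_swap(self, rng):
        """Relabeling bound/unbound (reflecting z about z_int in a symmetric
        box) negates dG exactly."""
        z_max = 20.0
        z = rng.uniform(0, z_max, 10_000) ** 1.3 % z_max
        a = binding_stats(ion_z_samples=z, z_int=8.0, z_max=z_max, temperature=300.0)
        b = binding_stats(ion_z_samples=z_max - z + 1e-12, z_int=z_max - 8.0,
                          z_max=z_max, temperature=300.0)
        assert a.delta_G == pytest.approx(-b.delta_G, abs=1e-9)

    def test_samples_and_histogram_agree(self, rng):
        """dG from raw samples equals dG from their histogram profile to
        within bin discretization."""
        box = BoxSpec(10.0, 10.0, 20.0)
        z = rng.uniform(0, box.lz, 30_000) ** 1.1 % box.lz
        traj = traj_with_z(z, box)
        prof = z_density_profile(traj, np.arange(z.size), bin_width=0.25, species="ion")
        a = binding_stats(ion_z_samples=z, z_int=8.0, z_max=box.lz, temperature=300.0)
        b = binding_stats(ion_profile=prof, z_int=8.0, z_max=box.lz, temperature=300.0)
        assert a.delta_G == pytest.approx(b.delta_G, abs=0.05)

    def test_no_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            binding_stats(ion_z_samples=np.array([]), z_int=5.0, z_max=10.0)
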