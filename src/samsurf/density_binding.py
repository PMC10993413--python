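"""z-resolved density profiles, bound-layer edge, regions, binding free energy.

The bound layer is the slab adjacent to the surface up to ``z_int``, the
height at which the ligand density falls to (numerically) zero.  With
``p_bound`` the fraction of ion observations below ``z_int`` and
``p_unbound = 1 - p_bound``, the free energy of moving an ion from the
bulk into the bound layer is::

    dG = -k_B * T * ln(p_bound / p_unbound)

in kJ/mol, with k_B the molar Boltzmann constant.  Degenerate occupancies
(p in {0, 1}) are flagged as unbounded rather than returned as infinities
by surprise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from samsurf.constants import KB_KJ_PER_MOL_K
from samsurf.traj_io import Trajectory


@dataclass
class DensityProfile:
    """Frame-averaged z density in atoms/A^3 on uniform bins.

    Satisfies the conservation identity
    area * sum(density * bin_width) == mean selected-atom count per frame.
    """

    bin_edges: np.ndarray  # A, length n_bins + 1
    density: np.ndarray  # atoms/A^3, length n_bins
    species: str
    n_frames: int
    area: float  # A^2, in-plane box area

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def mean_atom_count(self) -> float:
        """Mean number of selected atoms per frame implied by the profile."""
        return float(self.area * np.sum(self.density) * self.bin_width)


@dataclass
class RegionPartition:
    """Two boundaries z1 < z2 splitting the slab into three regions."""

    z1: float
    z2: float
    method: str  # "inflection" or "support"
    occupancy: tuple[float, float, float] | None = None


@dataclass
class BindingStats:
    """Bound-layer occupancy and binding free energy at temperature T."""

    z_int: float
    z_max: float
    p_bound: float
    p_unbound: float
    delta_G: float  # kJ/mol; +/-inf when unbounded_flag is set
    delta_G_kBT: float  # same quantity in units of k_B*T
    temperature: float
    n_observations: int
    unbounded_flag: bool = False
    k_B: float = KB_KJ_PER_MOL_K


def z_density_profile(
    traj: Trajectory,
    selection: np.ndarray,
    bin_width: float = 0.25,
    z_range: tuple[float, float] | None = None,
    species: str = "",
) -> DensityProfile:
    """Histogram selected atoms along z, averaged over frames.

    The z origin is the plane of the strand anchors (the restrained sulfur
    plane in the surface model); density is per-bin count / (area *
    bin_width * n_frames) in atoms/A^3.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    box = traj.box
    if z_range is None:
        z_range = (0.0, box.lz)
    lo, hi = z_range
    n_bins = max(1, int(math.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    z = traj.positions_of(selection)[:, :, 2].ravel()
    counts, _ = np.histogram(z, bins=edges)
    density = counts / (box.area_xy * bin_width * traj.n_frames)
    return DensityProfile(
        bin_edges=edges,
        density=density,
        species=species,
        n_frames=traj.n_frames,
        area=box.area_xy,
    )


def find_bound_layer_edge(ligand_profile: DensityProfile, epsilon_frac: float = 1e-3) -> float:
    """Height z_int at which the ligand density has (numerically) vanished.

    Scanning outward from the density maximum toward the bulk, z_int is the
    upper edge of the last bin whose density exceeds
    ``epsilon_frac * max(density)``; exact zero is unattainable for finite
    sampling, hence the relative threshold.
    """
    rho = ligand_profile.density
    if not np.any(rho > 0):
        raise ValueError("ligand profile is identically zero")
    peak = int(np.argmax(rho))
    thresh = epsilon_frac * rho[peak]
    above = np.flatnonzero(rho > thresh)
    above = above[above >= peak]
    last = int(above.max())
    if last == len(rho) - 1:
        raise ValueError(
            "ligand layer reaches the box edge: density never falls below "
            f"{epsilon_frac:g} of its maximum before z_max"
        )
    return float(ligand_profile.bin_edges[last + 1])


def partition_regions(
    profile: DensityProfile,
    method: str = "inflection",
    sigma_smooth_bins: float = 1.0,
    epsilon_frac: float = 1e-3,
    occupancy_profile: DensityProfile | None = None,
) -> RegionPartition:
    """Three-region split of the slab from a moiety (carboxylate) profile.

    "inflection": Gaussian-smooth the profile (sigma in bins), locate sign
    changes of the discrete second difference, and return the two
    inflections bracketing the global maximum — for a Gaussian density
    these sit at mu +/- sigma.  "support": return the extent of bins above
    ``epsilon_frac`` of the peak, i.e. boundaries that fully encompass the
    moiety density.

    Occupancies of a second species across the three regions are attached
    when ``occupancy_profile`` is given.
    """
    rho = profile.density.astype(float)
    z = profile.z_centers
    if method == "support":
        thresh = epsilon_frac * rho.max()
        above = np.flatnonzero(rho > thresh)
        if above.size == 0:
            raise ValueError("profile has no support above threshold")
        z1 = float(profile.bin_edges[above.min()])
        z2 = float(profile.bin_edges[above.max() + 1])
    elif method == "inflection":
        smooth = gaussian_filter1d(rho, sigma_smooth_bins, mode="nearest")
        d2 = np.diff(smooth, n=2)  # second difference, aligned with bins 1..n-2
        signs = np.sign(d2)
        flips = np.flatnonzero(np.diff(signs) != 0) + 1  # bin index of inflection
        peak = int(np.argmax(smooth))
        left = [i for i in flips if i < peak]
        right = [i for i in flips if i > peak]
        if not left or not right:
            raise ValueError(
                "fewer than two inflections bracket the density maximum; "
                "use method='support' for monotone or compact profiles"
            )
        z1 = float(z[max(left)])
        z2 = float(z[min(right)])
    else:
        raise ValueError(f"unknown region method {method!r}")
    occ = None
    if occupancy_profile is not None:
        zo = occupancy_profile.z_centers
        w = occupancy_profile.density
        tot = w.sum()
        if tot > 0:
            occ = (
                float(w[zo < z1].sum() / tot),
                float(w[(zo >= z1) & (zo < z2)].sum() / tot),
                float(w[zo >= z2].sum() / tot),
            )
    return RegionPartition(z1=z1, z2=z2, method=method, occupancy=occ)


def binding_stats(
    ion_z_samples: np.ndarray | None = None,
    ion_profile: DensityProfile | None = None,
    z_int: float = None,
    z_max: float = None,
    temperature: float = 300.0,
) -> BindingStats:
    """Bound-layer probability and binding free energy.

    From raw samples, p_bound is the fraction of ion observations with
    z < z_int; from a profile it is the density integral below z_int over
    the integral up to z_max (identical for histogrammed samples up to bin
    discretization).
    """
    if (ion_z_samples is None) == (ion_profile is None):
        raise ValueError("provide exactly one of ion_z_samples / ion_profile")
    if z_int is None or z_max is None or not z_int < z_max:
        raise ValueError(f"need z_int < z_max, got z_int={z_int}, z_max={z_max}")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    if ion_z_samples is not None:
        z = np.asarray(ion_z_samples, dtype=float).ravel()
        if z.size == 0:
            raise ValueError("no ion observations")
        n_obs = int(z.size)
        p_bound = float(np.mean(z < z_int))
    else:
        zc = ion_profile.z_centers
        w = ion_profile.density
        mask_all = zc <= z_max
        tot = float(w[mask_all].sum())
        if tot <= 0:
            raise ValueError("no ion observations in profile")
        p_bound = float(w[mask_all & (zc < z_int)].sum() / tot)
        n_obs = int(round(ion_profile.mean_atom_count() * ion_profile.n_frames))
    p_unbound = 1.0 - p_bound
    kT = KB_KJ_PER_MOL_K * temperature
    if p_bound <= 0.0 or p_unbound <= 0.0:
        dg = math.inf if p_bound <= 0.0 else -math.inf
        return BindingStats(
            z_int=z_int, z_max=z_max, p_bound=p_bound, p_unbound=p_unbound,
            delta_G=dg, delta_G_kBT=math.copysign(math.inf, dg),
            temperature=temperature, n_observations=n_obs, unbounded_flag=True,
        )
    dg = -kT * math.log(p_bound / p_unbound)
    return BindingStats(
        z_int=z_int, z_max=z_max, p_bound=p_bound, p_unbound=p_unbound,
        delta_G=dg, delta_G_kBT=dg / kT,
        temperature=temperature, n_observations=n_obs,
    )
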