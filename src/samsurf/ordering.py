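"""Pair and angular ordering of ions in the bound layer.

Ion-ion pair distributions restricted to a z slab are reported either as
a raw pair density in atoms/A^3 (counts per spherical shell volume,
matching the axis convention of surface-layer RDF plots) or as a
dimensionless g(r) normalized by the mean layer density with shell
volumes truncated analytically by the slab planes (spherical-cap
correction), so that an ideal gas gives g = 1 at all r.

Angular ordering is the distribution of the angle at a carboxylate
oxygen between the O->ion and O->C vectors, over all ion-oxygen contact
pairs within a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from samsurf.pbc import check_minimum_image_valid, minimum_image_displacement
from samsurf.traj_io import Trajectory, select


@dataclass
class PairDistribution:
    r_centers: np.ndarray  # A
    value: np.ndarray  # atoms/A^3 (pair_density) or dimensionless (normalized_gr)
    mode: str
    layer_bounds: tuple[float, float]
    n_frames: int
    n_pairs: int


@dataclass
class AngleDistribution:
    theta_centers: np.ndarray  # degrees in [0, 180]
    density: np.ndarray  # probability density per degree
    contact_cutoff: float
    n_contacts: int


def _truncated_shell_area(r: np.ndarray, d_below: float, d_above: float) -> np.ndarray:
    """Sphere-surface area 4*pi*r^2 minus the caps cut off by two planes.

    ``d_below``/``d_above`` are the distances from the sphere center to the
    lower/upper slab plane; a cap of height (r - d) is removed whenever
    r > d (cap area 2*pi*r*(r - d)).
    """
    area = 4.0 * np.pi * r**2
    area -= 2.0 * np.pi * r * np.clip(r - d_below, 0.0, None)
    area -= 2.0 * np.pi * r * np.clip(r - d_above, 0.0, None)
    return np.clip(area, 0.0, None)


def ion_ion_pair_distribution(
    traj: Trajectory,
    ion_selection: np.ndarray,
    layer_bounds: tuple[float, float],
    r_max: float,
    dr: float,
    mode: str = "pair_density",
) -> PairDistribution:
    """Distribution of ion-ion distances within a z slab.

    Distances use the minimum image in x,y; both partners must lie inside
    ``layer_bounds``.  See the module docstring for the two normalization
    modes.
    """
    if dr <= 0:
        raise ValueError("dr must be > 0")
    if mode not in ("pair_density", "normalized_gr"):
        raise ValueError(f"unknown mode {mode!r}")
    box = traj.box
    check_minimum_image_valid(r_max, box)
    z_lo, z_hi = layer_bounds
    edges = dr * np.arange(int(np.ceil(r_max / dr)) + 1)
    counts = np.zeros(len(edges) - 1)
    denom = np.zeros_like(counts)  # normalized_gr: expected ideal-gas pair counts
    n_ion_frames = 0
    n_frames_used = 0
    slab_volume = box.area_xy * (z_hi - z_lo)
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    total_pairs = 0
    for frame in traj.frames:
        pos = frame.positions[np.asarray(ion_selection, dtype=int)]
        in_layer = (pos[:, 2] >= z_lo) & (pos[:, 2] <= z_hi)
        p = pos[in_layer]
        n = len(p)
        if n < 2:
            continue
        n_frames_used += 1
        n_ion_frames += n
        d = minimum_image_displacement(p[:, None, :] - p[None, :, :], box)
        dist = np.linalg.norm(d, axis=-1)
        iu = np.triu_indices(n, k=1)
        vals = dist[iu]
        vals = vals[vals < edges[-1]]
        total_pairs += len(vals)
        c, _ = np.histogram(vals, bins=edges)
        counts += c
        if mode == "normalized_gr":
            rho = n / slab_volume
            for zi in p[:, 2]:
                shell = _truncated_shell_area(r_mid, zi - z_lo, z_hi - zi) * dr
                denom += 0.5 * rho * shell  # unordered pairs: N * rho * V / 2
    if n_frames_used == 0:
        raise ValueError("fewer than 2 ions in the layer in every frame")
    if mode == "pair_density":
        shell_vol = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        mean_n = n_ion_frames / n_frames_used
        value = 2.0 * counts / (mean_n * shell_vol * n_frames_used)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            value = np.where(denom > 0, counts / denom, 0.0)
    return PairDistribution(
        r_centers=r_mid, value=value, mode=mode,
        layer_bounds=(z_lo, z_hi), n_frames=n_frames_used, n_pairs=total_pairs,
    )


def ion_carboxylate_angle_distribution(
    traj: Trajectory,
    contact_cutoff: float = 3.2,
    bin_width_deg: float = 5.0,
    sin_corrected: bool = False,
) -> AngleDistribution:
    """Distribution of the ion / carboxylate-oxygen / carboxylate-carbon angle.

    For every frame and every (ion, oxygen) pair in minimum-image contact
    (distance <= ``contact_cutoff``), the angle at the oxygen between the
    O->ion and O->C vectors is accumulated and normalized to a probability
    density over degrees.  ``sin_corrected`` divides by sin(theta) to
    de-weight the isotropic solid-angle factor (off by default; the raw
    density is the field's plotting convention).
    """
    topo = traj.topology
    box = traj.box
    check_minimum_image_valid(contact_cutoff, box)
    ion_idx = select(topo, role="ion")
    o_idx = select(topo, role="carboxylate_O")
    if len(o_idx) == 0:
        raise ValueError("topology has no carboxylate_O atoms")
    if len(ion_idx) == 0:
        raise ValueError("topology has no ions")
    # partner carboxylate carbon of each oxygen (unique per molecule by invariant)
    c_of_mol = {}
    for i in select(topo, role="carboxylate_C"):
        c_of_mol[int(topo.molecule_id[i])] = int(i)
    c_idx = np.array([c_of_mol[int(topo.molecule_id[o])] for o in o_idx])

    edges = np.arange(0.0, 180.0 + bin_width_deg, bin_width_deg)
    edges[-1] = 180.0 + 1e-9  # include the exactly-collinear case
    counts = np.zeros(len(edges) - 1)
    n_contacts = 0
    for frame in traj.frames:
        pos = frame.positions
        d_io = minimum_image_displacement(
            pos[ion_idx][:, None, :] - pos[o_idx][None, :, :], box
        )
        dist = np.linalg.norm(d_io, axis=-1)
        ii, jj = np.nonzero(dist <= contact_cutoff)
        if len(ii) == 0:
            continue
        v_oi = d_io[ii, jj]  # O -> ion
        v_oc = minimum_image_displacement(pos[c_idx[jj]] - pos[o_idx[jj]], box)
        cosang = np.einsum("ij,ij->i", v_oi, v_oc) / (
            np.linalg.norm(v_oi, axis=1) * np.linalg.norm(v_oc, axis=1)
        )
        theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        c, _ = np.histogram(theta, bins=edges)
        counts += c
        n_contacts += len(theta)
    if n_contacts == 0:
        raise ValueError("zero ion-oxygen contacts within the cutoff")
    centers = 0.5 * (edges[:-1] + np.minimum(edges[1:], 180.0))
    if sin_corrected:
        weights = np.sin(np.radians(centers))
        weights[weights < 1e-12] = 1e-12
        counts = counts / weights
    density = counts / (counts.sum() * bin_width_deg)
    return AngleDistribution(
        theta_centers=centers, density=density,
        contact_cutoff=contact_cutoff, n_contacts=n_contacts,
    )
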