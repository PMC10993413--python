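"""Minimum-image geometry for slab-periodic boxes (periodic x,y; open z)."""

from __future__ import annotations

import numpy as np

from samsurf.traj_io import BoxSpec


def minimum_image_displacement(d: np.ndarray, box: BoxSpec) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Only axes flagged periodic in ``box`` are wrapped; for the default slab
    geometry that is x and y, while z separations are taken as-is.

    Parameters
    ----------
    d
        Array of displacement vectors, shape (..., 3).
    box
        Box specification with per-axis periodicity.
    """
    d = np.asarray(d, dtype=float).copy()
    for axis, (length, per) in enumerate(zip(box.lengths, box.periodic)):
        if per:
            d[..., axis] -= length * np.round(d[..., axis] / length)
    return d


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: BoxSpec) -> np.ndarray:
    """Pairwise minimum-image distances between position arrays ``a`` and ``b``.

    Returns an (len(a), len(b)) matrix.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    d = a[:, None, :] - b[None, :, :]
    d = minimum_image_displacement(d, box)
    return np.linalg.norm(d, axis=-1)


def wrap_positions(pos: np.ndarray, box: BoxSpec) -> np.ndarray:
    """Wrap coordinates into [0, L) along the periodic axes."""
    pos = np.asarray(pos, dtype=float).copy()
    for axis, (length, per) in enumerate(zip(box.lengths, box.periodic)):
        if per:
            pos[..., axis] = np.mod(pos[..., axis], length)
    return pos


def check_minimum_image_valid(cutoff: float, box: BoxSpec) -> None:
    """Raise if a distance cutoff is too large for unambiguous minimum image."""
    per_lengths = [length for length, per in zip(box.lengths, box.periodic) if per]
    if per_lengths and cutoff >= 0.5 * min(per_lengths):
        raise ValueError(
            f"cutoff {cutoff} A must be < half the smallest periodic box length "
            f"({0.5 * min(per_lengths):.3f} A) for the minimum-image convention"
        )


def neighbor_pairs_within(
    pos: np.ndarray, cutoff: float, box: BoxSpec
) -> np.ndarray:
    """Indices (i, j), i < j, of position pairs strictly closer than ``cutoff``.

    Uses a k-d tree with a toroidal box; the open z axis is emulated by a
    period far larger than the coordinate span, which never wraps.  Pairs at
    exactly the cutoff are excluded (strict inequality).
    """
    from scipy.spatial import cKDTree

    pos = np.asarray(pos, dtype=float)
    if len(pos) < 2:
        return np.empty((0, 2), dtype=int)
    check_minimum_image_valid(cutoff, box)
    shifted = wrap_positions(pos, box)
    boxsize = []
    for axis, (length, per) in enumerate(zip(box.lengths, box.periodic)):
        if per:
            boxsize.append(length)
        else:
            lo = shifted[:, axis].min()
            shifted[:, axis] -= lo
            span = shifted[:, axis].max()
            # period > 2*(span+cutoff) guarantees no spurious wrap in z
            boxsize.append(2.0 * (span + cutoff) + 1.0)
    tree = cKDTree(shifted, boxsize=boxsize)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=int)
    d = np.linalg.norm(
        minimum_image_displacement(pos[pairs[:, 0]] - pos[pairs[:, 1]], box), axis=-1
    )
    return pairs[d < cutoff]
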