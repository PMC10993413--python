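"""Single-linkage distance-cutoff clustering of ligand moieties under PBC.

Two molecules belong to the same cluster when ANY pair of their selected
atoms lies strictly closer than the cutoff under the minimum-image
convention (periodic x,y; open z), and clusters are the connected
components of that link graph.  This is the classic distance-cutoff
molecular clustering used for phenyl-ring aggregates (4 A between ring
carbons) and carboxylate aggregates (5 A between any carboxylate carbon
or oxygen); the same machinery with ions treated as single-atom molecules
yields mixed ion-carboxylate clusters.

A distance exactly equal to the cutoff does NOT link (documented
tie-break).  Singletons count as clusters of size 1 by default, which is
required for sparse systems whose mean cluster size is barely above 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import DisjointSet

from samsurf.pbc import check_minimum_image_valid, neighbor_pairs_within
from samsurf.traj_io import Frame, Topology, select


@dataclass(frozen=True)
class ClusterParams:
    """Linkage cutoff (A), linking atom roles, and minimum reported size."""

    cutoff: float
    role_set: frozenset[str] = frozenset({"phenyl_C"})
    min_size: int = 1

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be > 0, got {self.cutoff}")
        if not self.role_set:
            raise ValueError("role_set must be nonempty")
        if self.min_size < 1:
            raise ValueError(f"min_size must be >= 1, got {self.min_size}")


@dataclass
class ClusterPartition:
    """Per-frame partition of participating molecules into clusters.

    ``clusters`` holds sets of molecule keys; for mixed ion/moiety
    clustering the keys are ("ion", atom_index) and ("mol", molecule_id)
    tuples and ``compositions`` carries per-cluster (n_ions, n_moieties).
    """

    frame_index: int
    clusters: list[set]
    compositions: list[tuple[int, int]] | None = None

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.clusters], dtype=int)

    def validate_partition(self) -> None:
        all_members: list = []
        for c in self.clusters:
            all_members.extend(c)
        if len(all_members) != len(set(all_members)):
            raise AssertionError("clusters are not disjoint")


@dataclass
class ClusterSizeDistribution:
    """Pooled cluster-size probabilities over an analysis window."""

    probabilities: dict[int, float]
    mean_size: float
    n_observations: int

    def as_series(self):
        import pandas as pd

        s = pd.Series(self.probabilities, name="probability").sort_index()
        s.index.name = "size"
        return s


def _connected_components(keys: Sequence, links: Iterable[tuple]) -> list[set]:
    ds = DisjointSet(keys)
    for a, b in links:
        ds.merge(a, b)
    return [set(sub) for sub in ds.subsets()]


def cluster_frame(frame: Frame, topology: Topology, params: ClusterParams) -> ClusterPartition:
    """Single-linkage molecule clustering of one frame.

    Molecules owning at least one atom with a role in ``params.role_set``
    participate; each appears in exactly one cluster of the result.
    """
    check_minimum_image_valid(params.cutoff, frame.box)
    idx = select(topology, role=params.role_set)
    if len(idx) == 0:
        raise ValueError(f"no atoms with roles {sorted(params.role_set)} in topology")
    mols = topology.molecule_id[idx]
    pos = frame.positions[idx]
    pairs = neighbor_pairs_within(pos, params.cutoff, frame.box)
    links = (
        (mols[i], mols[j]) for i, j in pairs if mols[i] != mols[j]
    )
    keys = list(np.unique(mols))
    clusters = _connected_components(keys, links)
    part = ClusterPartition(frame_index=0, clusters=clusters)
    return part


def ion_moiety_clusters(
    frame: Frame,
    topology: Topology,
    cutoff: float,
    ion_role: str = "ion",
    moiety_roles: Iterable[str] = ("carboxylate_C", "carboxylate_O"),
) -> ClusterPartition:
    """Mixed clusters of ions and ligand moieties (e.g. ion-carboxylate).

    Each ion atom is treated as its own single-atom molecule; moiety atoms
    group by molecule id as usual.  Cluster compositions (n_ions,
    n_moiety_molecules) are attached to the partition.
    """
    moiety_roles = frozenset(moiety_roles)
    check_minimum_image_valid(cutoff, frame.box)
    ion_idx = select(topology, role=ion_role)
    moi_idx = select(topology, role=moiety_roles)
    if len(moi_idx) == 0 and len(ion_idx) == 0:
        raise ValueError("no ion or moiety atoms to cluster")
    keys: list = [("ion", int(i)) for i in ion_idx]
    keys += [("mol", int(m)) for m in np.unique(topology.molecule_id[moi_idx])]
    atom_idx = np.concatenate([ion_idx, moi_idx]).astype(int)
    atom_key = [("ion", int(i)) for i in ion_idx] + [
        ("mol", int(topology.molecule_id[i])) for i in moi_idx
    ]
    pos = frame.positions[atom_idx]
    pairs = neighbor_pairs_within(pos, cutoff, frame.box)
    links = ((atom_key[i], atom_key[j]) for i, j in pairs if atom_key[i] != atom_key[j])
    clusters = _connected_components(keys, links)
    compositions = [
        (sum(1 for k in c if k[0] == "ion"), sum(1 for k in c if k[0] == "mol"))
        for c in clusters
    ]
    return ClusterPartition(frame_index=0, clusters=clusters, compositions=compositions)


def cluster_size_distribution(
    partitions: Iterable[ClusterPartition], min_size: int = 1
) -> ClusterSizeDistribution:
    """Pool clusters across frames into a size distribution.

    Every cluster in every frame is one observation; P(s) is the fraction
    of observations of size s after discarding sizes below ``min_size``,
    and the mean is sum(s * P(s)).
    """
    counts: dict[int, int] = {}
    for part in partitions:
        for s in part.sizes:
            s = int(s)
            if s >= min_size:
                counts[s] = counts.get(s, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no clusters remain after min_size filtering")
    probs = {s: c / total for s, c in sorted(counts.items())}
    mean = sum(s * p for s, p in probs.items())
    return ClusterSizeDistribution(probabilities=probs, mean_size=mean, n_observations=total)


def brute_force_cluster_frame(
    frame: Frame, topology: Topology, params: ClusterParams
) -> ClusterPartition:
    """Reference single-linkage clustering by all-pairs BFS (test oracle).

    Independent of the cell-list/union-find path: builds the full molecule
    adjacency from the dense minimum-image distance matrix and walks the
    graph breadth-first.
    """
    from collections import deque

    from samsurf.pbc import minimum_image_distance

    idx = select(topology, role=params.role_set)
    mols = topology.molecule_id[idx]
    keys = list(np.unique(mols))
    pos = frame.positions[idx]
    dmat = minimum_image_distance(pos, pos, frame.box)
    adj: dict[int, set[int]] = {k: set() for k in keys}
    n = len(idx)
    for i in range(n):
        for j in range(i + 1, n):
            if mols[i] != mols[j] and dmat[i, j] < params.cutoff:
                adj[mols[i]].add(mols[j])
                adj[mols[j]].add(mols[i])
    seen: set[int] = set()
    clusters = []
    for k in keys:
        if k in seen:
            continue
        comp = set()
        queue = deque([k])
        while queue:
            cur = queue.popleft()
            if cur in comp:
                continue
            comp.add(cur)
            queue.extend(adj[cur] - comp)
        seen |= comp
        clusters.append(comp)
    return ClusterPartition(frame_index=0, clusters=clusters)


def partitions_equal(a: ClusterPartition, b: ClusterPartition) -> bool:
    """True when two partitions contain exactly the same clusters."""
    fa = {frozenset(c) for c in a.clusters}
    fb = {frozenset(c) for c in b.clusters}
    return fa == fb
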