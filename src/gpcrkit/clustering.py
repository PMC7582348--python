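"""Pairwise-RMSD matrices, GROMOS trajectory clustering and pose clustering.

The GROMOS algorithm is the greedy neighbor-count scheme: repeatedly take
the unassigned label with the most unassigned neighbors within the cutoff
as the representative of a new cluster, remove it and its neighbors, and
iterate.  Removed members never count as neighbors in later rounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import kabsch_superpose
from .structure import Selection, Trajectory, select

__all__ = [
    "DistanceMatrix",
    "Cluster",
    "ClusterResult",
    "rmsd_matrix",
    "gromos_cluster",
    "representative_structure",
    "pose_cluster",
]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise RMSD values with explicit units."""

    values: np.ndarray
    labels: list = field(default_factory=list)
    units: str = "angstrom"  # "angstrom" or "nm"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not self.labels:
            self.labels = list(range(n))
        if len(self.labels) != n:
            raise ValueError("label count mismatch")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        if np.max(np.abs(np.diagonal(self.values))) > 1e-9:
            raise ValueError("diagonal must be zero")
        if np.max(np.abs(self.values - self.values.T)) > 1e-9:
            raise ValueError("matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Cluster:
    members: list
    representative: object
    size: int = 0

    def __post_init__(self):
        self.size = len(self.members)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    cutoff: float
    units: str = "angstrom"

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]

    def membership(self) -> dict:
        out = {}
        for k, c in enumerate(self.clusters):
            for m in c.members:
                out[m] = k
        return out

    def by_size(self) -> list[Cluster]:
        """Clusters sorted largest first (ties keep formation order)."""
        return sorted(self.clusters, key=lambda c: -c.size)

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "units": self.units,
            "n_clusters": self.n_clusters,
            "clusters": [
                {"members": list(c.members), "size": c.size,
                 "representative": c.representative}
                for c in self.clusters
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)
            fh.write("\n")


def rmsd_matrix(traj: Trajectory, selection: Selection | str = "name CA",
                superpose: bool = True,
                units: str = "angstrom") -> DistanceMatrix:
    """All-vs-all RMSD over a selection; optionally Kabsch-superposed."""
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    idx = select(traj, selection)
    if not idx:
        raise ValueError("rmsd_matrix: empty selection")
    coords = [traj.frames[f][idx] for f in range(traj.n_frames)]
    n = traj.n_frames
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if superpose:
                _, _, r = kabsch_superpose(coords[i], coords[j])
            else:
                r = float(np.sqrt(np.mean(
                    np.sum((coords[i] - coords[j]) ** 2, axis=1))))
            values[i, j] = values[j, i] = r
    if units == "nm":
        values = values / 10.0
    return DistanceMatrix(values=values, labels=list(range(n)), units=units)


def gromos_cluster(matrix: DistanceMatrix, cutoff: float) -> ClusterResult:
    """Greedy neighbor-count clustering of a distance matrix.

    Ties in the neighbor count are broken by the lowest label position.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = matrix.n
    within = matrix.values <= cutoff
    remaining = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while remaining.any():
        # neighbor counts among unassigned labels (self included)
        counts = (within & remaining).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index tie
        members_idx = np.nonzero(within[center] & remaining)[0]
        clusters.append(Cluster(
            members=[matrix.labels[i] for i in members_idx],
            representative=matrix.labels[center],
        ))
        remaining[members_idx] = False
    return ClusterResult(clusters=clusters, cutoff=cutoff,
                         units=matrix.units)


def representative_structure(result: ClusterResult, cluster_rank: int = 1):
    """Representative label of the rank-th largest cluster (1 = largest)."""
    ranked = result.by_size()
    if not 1 <= cluster_rank <= len(ranked):
        raise IndexError(
            f"cluster_rank {cluster_rank} out of range (1..{len(ranked)})")
    return ranked[cluster_rank - 1].representative


def pose_cluster(pose_set, rmsd_cutoff: float = 2.0):
    """Cluster each ligand's docked poses at an RMSD cutoff (no fitting).

    Poses of one ligand share the receptor frame, so the RMSD is computed
    without superposition, on heavy atoms.  Returns
    ``(results, representatives)``: per-ligand :class:`ClusterResult` and
    the representative pose id — the member of the largest cluster closest
    to that cluster's coordinate centroid (ties -> lowest pose id).
    """
    results: dict[str, ClusterResult] = {}
    representatives: dict[str, str] = {}
    for ligand_id, poses in pose_set.by_ligand().items():
        if not poses:
            raise ValueError(f"ligand {ligand_id} has no poses")
        heavy = [i for i, el in enumerate(poses[0].elements)
                 if el.upper() != "H"]
        coords = []
        for p in poses:
            if len(p.elements) != len(poses[0].elements):
                raise ValueError(
                    f"ligand {ligand_id}: inconsistent atom counts")
            coords.append(np.asarray(p.coords)[heavy])
        n = len(poses)
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                r = float(np.sqrt(np.mean(
                    np.sum((coords[i] - coords[j]) ** 2, axis=1))))
                values[i, j] = values[j, i] = r
        matrix = DistanceMatrix(values=values,
                                labels=[p.pose_id for p in poses])
        result = gromos_cluster(matrix, rmsd_cutoff)
        results[ligand_id] = result
        top = result.by_size()[0]
        member_pos = [matrix.labels.index(m) for m in top.members]
        centroid = np.mean([coords[i] for i in member_pos], axis=0)
        dists = [float(np.sqrt(np.mean(
            np.sum((coords[i] - centroid) ** 2, axis=1))))
            for i in member_pos]
        best = min(range(len(member_pos)),
                   key=lambda k: (dists[k], top.members[k]))
        representatives[ligand_id] = top.members[best]
    return results, representatives


def cluster_summary(results: dict, complexes: dict | None = None
                    ) -> pd.DataFrame:
    """Table-style summary: one row per clustered entity."""
    rows = []
    for name, res in results.items():
        top = res.by_size()[0]
        rows.append({
            "complex": name,
            "cluster1_label": top.representative,
            "cluster1_size": top.size,
            "cutoff": res.cutoff,
            "units": res.units,
            "n_clusters": res.n_clusters,
        })
    return pd.DataFrame(rows)
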