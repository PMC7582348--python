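"""Ligand pose libraries with planted pharmacophoric clusters.

Each planted cluster has a feature type, a spatial centroid and a spread;
ligands assigned to it are small template fragments that carry exactly
that chemistry (ether oxygen for HAc, hydroxyl for HDn, benzene for Arm,
butane for Hph, methylammonium for PIn, acetate for NIn).  Every ligand
gets several near-duplicate poses (tight jitter) and optionally displaced
outlier poses, so pose clustering at 2 Å has known structure.  The truth
table records, per cluster, every feature type the template implies and
its planted centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..poses import LigandPose, PoseSet

__all__ = ["PoseClusterSpec", "PoseLibrarySpec", "make_pose_library",
           "TEMPLATES"]

_AR = 12  # aromatic bond order tag


@dataclass(frozen=True)
class _Template:
    elements: tuple
    coords: tuple                 # anchor (feature position) at origin
    bonds: tuple
    charges: tuple
    aromatic: tuple
    #: feature types this fragment contributes at (offset from anchor)
    feature_truth: tuple          # ((type, offset 3-vector), ...)


def _hexagon(r=1.39):
    return tuple(
        (r * np.cos(a), r * np.sin(a), 0.0)
        for a in np.linspace(0, 2 * np.pi, 6, endpoint=False))


TEMPLATES: dict[str, _Template] = {
    # dimethyl ether: lone-pair O, no H -> single HAc at O
    "HAc": _Template(
        elements=("C", "O", "C"),
        coords=((-1.17, 0.66, 0.0), (0.0, 0.0, 0.0), (1.17, 0.66, 0.0)),
        bonds=((0, 1, 1), (1, 2, 1)),
        charges=(0, 0, 0), aromatic=(False, False, False),
        feature_truth=(("HAc", (0.0, 0.0, 0.0)),),
    ),
    # methanol: O-H donor that also keeps its lone pairs
    "HDn": _Template(
        elements=("C", "O"),
        coords=((-1.43, 0.0, 0.0), (0.0, 0.0, 0.0)),
        bonds=((0, 1, 1),),
        charges=(0, 0), aromatic=(False, False),
        feature_truth=(("HDn", (0.0, 0.0, 0.0)),
                       ("HAc", (0.0, 0.0, 0.0))),
    ),
    # benzene: one aromatic ring centroid
    "Arm": _Template(
        elements=("C",) * 6,
        coords=_hexagon(),
        bonds=tuple((i, (i + 1) % 6, _AR) for i in range(6)),
        charges=(0,) * 6, aromatic=(True,) * 6,
        feature_truth=(("Arm", (0.0, 0.0, 0.0)),),
    ),
    # n-butane chain centered at origin
    "Hph": _Template(
        elements=("C", "C", "C", "C"),
        coords=((-1.95, -0.4, 0.0), (-0.65, 0.4, 0.0),
                (0.65, -0.4, 0.0), (1.95, 0.4, 0.0)),
        bonds=((0, 1, 1), (1, 2, 1), (2, 3, 1)),
        charges=(0, 0, 0, 0), aromatic=(False,) * 4,
        feature_truth=(("Hph", (0.0, 0.0, 0.0)),),
    ),
    # methylammonium: protonated amine; the charged N is excluded from
    # HAc/HDn typing under the default rules, so the truth is PIn only
    "PIn": _Template(
        elements=("C", "N"),
        coords=((-1.49, 0.0, 0.0), (0.0, 0.0, 0.0)),
        bonds=((0, 1, 1),),
        charges=(0, 1), aromatic=(False, False),
        feature_truth=(("PIn", (0.0, 0.0, 0.0)),),
    ),
    # acetate: carboxylate centroid at the anchor
    "NIn": _Template(
        elements=("C", "C", "O", "O"),
        coords=((-2.13, 0.0, 0.0), (-0.63, 0.0, 0.0),
                (0.0, 1.06, 0.0), (0.0, -1.06, 0.0)),
        bonds=((0, 1, 1), (1, 2, 2), (1, 3, 1)),
        charges=(0, 0, 0, -1), aromatic=(False,) * 4,
        feature_truth=(("NIn", (0.0, 0.0, 0.0)),),
    ),
}


@dataclass
class PoseClusterSpec:
    feature_type: str
    centroid: np.ndarray
    spatial_sd: float = 0.3
    n_members: int = 10

    def __post_init__(self):
        if self.feature_type not in TEMPLATES:
            raise ValueError(
                f"unknown feature type {self.feature_type!r}")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.spatial_sd < 0:
            raise ValueError("spatial sd must be >= 0")
        self.centroid = np.asarray(self.centroid, dtype=float)


@dataclass
class PoseLibrarySpec:
    clusters: list[PoseClusterSpec]
    pose_jitter_sd: float = 0.2   # rigid translation jitter per extra pose
    n_poses: int = 4              # near-duplicate poses per ligand
    n_outlier_poses: int = 0      # displaced poses per ligand
    outlier_shift: float = 8.0
    seed: int = 0
    pki_range: tuple[float, float] = (5.0, 9.7)

    def __post_init__(self):
        if not self.clusters:
            raise ValueError("need at least one cluster")
        if self.pose_jitter_sd < 0:
            raise ValueError("pose jitter sd must be >= 0")
        if self.n_poses < 1:
            raise ValueError("n_poses must be >= 1")

    @property
    def n_ligands(self) -> int:
        return sum(c.n_members for c in self.clusters)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_pose_library(spec: PoseLibrarySpec):
    """Generate the pose library and its ground truth.

    Returns ``(pose_set, truth)`` where truth is a dict with keys
    ``clusters`` (planted feature types/centroids and member ligands) and
    ``ligands`` (per ligand: anchor position, main/outlier pose ids).
    """
    rng = np.random.default_rng(spec.seed)
    poses: list[LigandPose] = []
    truth_clusters = []
    truth_ligands: dict[str, dict] = {}
    ligand_no = 0
    for ci, cluster in enumerate(spec.clusters):
        template = TEMPLATES[cluster.feature_type]
        member_ids = []
        for _ in range(cluster.n_members):
            ligand_id = f"L{ligand_no:03d}"
            ligand_no += 1
            member_ids.append(ligand_id)
            anchor = cluster.centroid + rng.normal(
                0.0, cluster.spatial_sd, size=3)
            rot = _random_rotation(rng)
            base = np.asarray(template.coords) @ rot.T + anchor
            pki = float(rng.uniform(*spec.pki_range))
            main_ids, outlier_ids = [], []
            for p in range(spec.n_poses):
                shift = np.zeros(3) if p == 0 else rng.normal(
                    0.0, spec.pose_jitter_sd, size=3)
                pose_id = f"p{p}"
                main_ids.append(pose_id)
                poses.append(LigandPose(
                    ligand_id=ligand_id, pose_id=pose_id,
                    elements=list(template.elements),
                    coords=base + shift,
                    bonds=list(template.bonds),
                    charges=list(template.charges),
                    aromatic=list(template.aromatic),
                    pki=pki,
                ))
            for p in range(spec.n_outlier_poses):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                pose_id = f"o{p}"
                outlier_ids.append(pose_id)
                poses.append(LigandPose(
                    ligand_id=ligand_id, pose_id=pose_id,
                    elements=list(template.elements),
                    coords=base + u * spec.outlier_shift,
                    bonds=list(template.bonds),
                    charges=list(template.charges),
                    aromatic=list(template.aromatic),
                    pki=pki,
                ))
            truth_ligands[ligand_id] = {
                "cluster": ci,
                "anchor": anchor.tolist(),
                "main_pose_ids": main_ids,
                "outlier_pose_ids": outlier_ids,
            }
        truth_clusters.append({
            "index": ci,
            "planted_type": cluster.feature_type,
            "feature_types": sorted({t for t, _ in template.feature_truth}),
            "centroid": cluster.centroid.tolist(),
            "members": member_ids,
        })
    truth = {"clusters": truth_clusters, "ligands": truth_ligands,
             "seed": spec.seed}
    return PoseSet(poses=poses), truth
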