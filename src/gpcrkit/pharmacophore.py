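"""Pharmacophoric feature extraction and consensus interaction models.

Features are typed rule-based from the molecular graph of each docked
pose — hydrogen-bond acceptors (HAc), donors (HDn), aromatic rings (Arm),
hydrophobic groups (Hph) and positive/negative ionizable groups
(PIn/NIn).  Features pooled over one representative pose per ligand are
clustered per type ("nature") with a deterministic partition-around-
medoids (BUILD + SWAP) in a position ⊕ size metric, and each surviving
consensus element is annotated with the receptor residues within an
annotation radius (default 5 Å).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .poses import LigandPose, PoseSet
from .structure import Structure

__all__ = [
    "FEATURE_TYPES",
    "FeatureRules",
    "PharmacophoreFeature",
    "ConsensusElement",
    "ConsensusModel",
    "extract_features",
    "pam_kmedoids",
    "silhouette_mean",
    "choose_k",
    "build_consensus",
    "compare_models",
]

FEATURE_TYPES = ("HAc", "HDn", "Arm", "Hph", "PIn", "NIn")

_DEFAULT_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3}

_AROMATIC_ORDER = 12


@dataclass
class FeatureRules:
    """Tunable knobs of the typing rules."""

    point_radius: float = 1.0      # HAc/HDn/PIn/NIn feature radius, Å
    group_radius: float = 1.5      # Arm/Hph feature radius, Å
    hph_min_carbons: int = 3       # minimum size of a hydrophobic patch
    #: atoms that belong to an ionizable group are not typed HAc/HDn
    charged_excludes_polar: bool = True


@dataclass(frozen=True)
class PharmacophoreFeature:
    type: str
    position: np.ndarray
    radius: float
    ligand_id: str = ""
    pose_id: str = ""
    atom_indices: tuple[int, ...] = ()

    def __post_init__(self):
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.type!r}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        object.__setattr__(self, "position",
                           np.asarray(self.position, dtype=float))


class _MolGraph:
    """Connectivity helpers over a LigandPose."""

    def __init__(self, pose: LigandPose):
        self.pose = pose
        n = pose.n_atoms
        self.neighbors: list[list[int]] = [[] for _ in range(n)]
        self.bond_order: dict[tuple[int, int], int] = {}
        for i, j, order in pose.bonds:
            self.neighbors[i].append(j)
            self.neighbors[j].append(i)
            self.bond_order[(min(i, j), max(i, j))] = order

    def order(self, i: int, j: int) -> int:
        return self.bond_order[(min(i, j), max(i, j))]

    def degree(self, i: int) -> int:
        return len(self.neighbors[i])

    def valence_used(self, i: int) -> int:
        total = 0
        for j in self.neighbors[i]:
            o = self.order(i, j)
            total += 1 if o == _AROMATIC_ORDER else o
        # two aromatic bonds contribute 3 in the usual bookkeeping
        n_arom = sum(1 for j in self.neighbors[i]
                     if self.order(i, j) == _AROMATIC_ORDER)
        if n_arom >= 2:
            total += 1
        return total

    def rings(self) -> list[list[int]]:
        """Smallest rings via a cycle basis of the bond graph."""
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(range(self.pose.n_atoms))
        g.add_edges_from((i, j) for i, j, _ in self.pose.bonds)
        return [sorted(c) for c in nx.minimum_cycle_basis(g)]


def _total_h(graph: _MolGraph, i: int) -> int:
    """Explicit plus valence-implied hydrogens on heavy atom i."""
    pose = graph.pose
    el = pose.elements[i].capitalize()
    valence = _DEFAULT_VALENCE.get(el, 0)
    if el in ("N", "O"):
        valence += pose.charges[i]
    explicit = sum(1 for j in graph.neighbors[i]
                   if pose.elements[j].upper() == "H")
    implied = max(0, valence - graph.valence_used(i))
    return max(explicit, implied)


def extract_features(pose: LigandPose,
                     rules: FeatureRules | None = None
                     ) -> list[PharmacophoreFeature]:
    """Rule-based pharmacophoric typing of one pose.

    See the module docstring for the feature vocabulary; positions are
    atom coordinates for point features and group centroids for ring,
    hydrophobic and ionizable-group features.
    """
    rules = rules or FeatureRules()
    graph = _MolGraph(pose)
    elements = [e.upper() for e in pose.elements]
    feats: list[PharmacophoreFeature] = []

    def add(ftype, position, atoms, radius):
        feats.append(PharmacophoreFeature(
            type=ftype, position=np.asarray(position, dtype=float),
            radius=radius, ligand_id=pose.ligand_id, pose_id=pose.pose_id,
            atom_indices=tuple(int(a) for a in atoms)))

    # --- ionizable groups -------------------------------------------------
    charged_atoms: set[int] = set()
    # negative: carboxylate / sulfonate / phosphate or explicit charge < 0
    done_neg: set[int] = set()
    for i, el in enumerate(elements):
        if el in ("C", "S", "P"):
            term_o = [j for j in graph.neighbors[i]
                      if elements[j] == "O" and graph.degree(j) == 1]
            if len(term_o) >= 2 and (
                    any(pose.charges[j] < 0 for j in term_o)
                    or el in ("S", "P")
                    or any(graph.order(i, j) == 2 for j in term_o)):
                centroid = pose.coords[term_o].mean(axis=0)
                add("NIn", centroid, term_o, rules.point_radius)
                done_neg.update(term_o)
                charged_atoms.update(term_o)
                charged_atoms.add(i)
    for i, q in enumerate(pose.charges):
        if q < 0 and i not in done_neg:
            add("NIn", pose.coords[i], [i], rules.point_radius)
            charged_atoms.add(i)
    # positive: guanidinium/amidinium, protonatable amines, charge > 0
    done_pos: set[int] = set()
    for i, el in enumerate(elements):
        if el == "C":
            n_nbrs = [j for j in graph.neighbors[i] if elements[j] == "N"]
            has_o = any(elements[j] == "O" for j in graph.neighbors[i])
            if len(n_nbrs) >= 2 and not has_o and all(
                    not pose.aromatic[j] for j in n_nbrs):
                # amidine/guanidine carbon
                add("PIn", pose.coords[i], [i] + n_nbrs, rules.point_radius)
                done_pos.update(n_nbrs)
                charged_atoms.update(n_nbrs)
                charged_atoms.add(i)
    for i, el in enumerate(elements):
        if el != "N" or i in done_pos:
            continue
        if pose.charges[i] > 0:
            add("PIn", pose.coords[i], [i], rules.point_radius)
            charged_atoms.add(i)
            continue
        if pose.aromatic[i]:
            continue
        heavy_nbrs = [j for j in graph.neighbors[i]
                      if elements[j] != "H"]
        if _is_amide_n(graph, i, elements):
            continue
        # neutral sp3 amine bonded only to carbons: protonatable
        if heavy_nbrs and all(elements[j] == "C" for j in heavy_nbrs) \
                and all(graph.order(i, j) == 1 for j in heavy_nbrs) \
                and not any(
                    any(graph.order(j, k) == 2 and elements[k] in ("O", "N")
                        for k in graph.neighbors[j])
                    for j in heavy_nbrs):
            add("PIn", pose.coords[i], [i], rules.point_radius)
            charged_atoms.add(i)

    # --- hydrogen bonding -------------------------------------------------
    for i, el in enumerate(elements):
        if el not in ("N", "O"):
            continue
        if rules.charged_excludes_polar and i in charged_atoms:
            continue
        positively_charged = pose.charges[i] > 0
        n_h = _total_h(graph, i)
        is_amide = el == "N" and _is_amide_n(graph, i, elements)
        aromatic_nh = el == "N" and pose.aromatic[i] and n_h > 0
        # acceptor: lone pair available, not positive, not amide/pyrrole N
        if not positively_charged and not is_amide and not aromatic_nh:
            add("HAc", pose.coords[i], [i], rules.point_radius)
        if n_h >= 1:
            add("HDn", pose.coords[i], [i], rules.point_radius)

    # --- aromatic rings ---------------------------------------------------
    for ring in graph.rings():
        if len(ring) >= 3 and all(pose.aromatic[i] for i in ring):
            add("Arm", pose.coords[ring].mean(axis=0), ring,
                rules.group_radius)

    # --- hydrophobic patches ---------------------------------------------
    nonpolar = {i for i, el in enumerate(elements)
                if el == "C" and not pose.aromatic[i]
                and not any(elements[j] in ("N", "O", "S", "P")
                            for j in graph.neighbors[i])
                and i not in charged_atoms}
    seen: set[int] = set()
    for start in sorted(nonpolar):
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        queue = [start]
        while queue:
            cur = queue.pop()
            for j in graph.neighbors[cur]:
                if j in nonpolar and j not in seen:
                    seen.add(j)
                    comp.append(j)
                    queue.append(j)
        if len(comp) >= rules.hph_min_carbons:
            comp = sorted(comp)
            add("Hph", pose.coords[comp].mean(axis=0), comp,
                rules.group_radius)

    return feats


def _is_amide_n(graph: _MolGraph, i: int, elements) -> bool:
    for j in graph.neighbors[i]:
        if elements[j] != "C":
            continue
        for k in graph.neighbors[j]:
            if k != i and elements[k] == "O" and graph.order(j, k) == 2:
                return True
    return False


# ---------------------------------------------------------------------------
# Partition around medoids
# ---------------------------------------------------------------------------

def feature_distance_matrix(positions, radii,
                            size_weight: float = 1.0) -> np.ndarray:
    """Euclidean position distance plus ``size_weight * |Δradius|``."""
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    d = cdist(positions, positions)
    d += size_weight * np.abs(radii[:, None] - radii[None, :])
    return d


def pam_kmedoids(dist: np.ndarray, k: int):
    """Deterministic PAM: greedy BUILD then best-improvement SWAP.

    Returns ``(medoids, assignment, total_cost)``; all ties are broken by
    the lowest index, so results are reproducible.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")

    # BUILD: add the medoid that minimizes total cost at each step
    medoids: list[int] = []
    for _ in range(k):
        best_cost, best_idx = None, None
        for cand in range(n):
            if cand in medoids:
                continue
            trial = medoids + [cand]
            cost = float(dist[:, trial].min(axis=1).sum())
            if best_cost is None or cost < best_cost - 1e-12:
                best_cost, best_idx = cost, cand
        medoids.append(best_idx)
    medoids.sort()
    cost = float(dist[:, medoids].min(axis=1).sum())

    # SWAP: accept the single best cost-reducing swap, repeat
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for cand in range(n):
                if cand in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = cand
                new_cost = float(dist[:, trial].min(axis=1).sum())
                delta = new_cost - cost
                if delta < best[0] - 1e-12:
                    best = (delta, mi, cand)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            medoids.sort()
            cost = float(dist[:, medoids].min(axis=1).sum())
            improved = True

    assignment = np.asarray(medoids)[np.argmin(dist[:, medoids], axis=1)]
    return list(medoids), assignment, cost


def silhouette_mean(dist: np.ndarray, assignment) -> float:
    """Mean silhouette coefficient from a precomputed distance matrix."""
    from sklearn.metrics import silhouette_score
    return float(silhouette_score(dist, np.asarray(assignment),
                                  metric="precomputed"))


def choose_k(dist: np.ndarray, k_range=None,
             min_silhouette: float = 0.6) -> int:
    """k maximizing the mean silhouette over PAM solutions.

    The silhouette is undefined for k=1, so a single unstructured cloud
    is recognised by thresholding: when even the best k ≥ 2 scores below
    *min_silhouette* the data are treated as one cluster (splitting a
    single Gaussian blob tops out near 0.4, well-separated blobs score
    above 0.9).  Also falls back to k=1 when fewer than 3 points or an
    empty range make the silhouette undefined.  Ties go to the smallest k.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if k_range is None:
        k_range = range(2, min(n - 1, 8) + 1)
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        return 1
    best_k, best_s = 1, -np.inf
    for k in k_range:
        _, assignment, _ = pam_kmedoids(dist, k)
        if len(set(assignment.tolist())) < 2:
            continue
        s = silhouette_mean(dist, assignment)
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_s < min_silhouette:
        return 1
    return best_k


# ---------------------------------------------------------------------------
# Consensus model
# ---------------------------------------------------------------------------

@dataclass
class ConsensusElement:
    type: str
    centroid: np.ndarray
    radius: float
    support: int
    ligand_ids: list[str] = field(default_factory=list)
    residues: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "type": self.type,
            "centroid": [round(float(x), 4) for x in self.centroid],
            "radius": round(float(self.radius), 4),
            "support": self.support,
            "ligand_ids": self.ligand_ids,
            "residues": self.residues,
        }


@dataclass
class ConsensusModel:
    elements: list[ConsensusElement]
    n_ligands: int
    min_support: int
    annotation_radius: float

    def to_dict(self) -> dict:
        return {
            "n_ligands": self.n_ligands,
            "min_support": self.min_support,
            "annotation_radius": self.annotation_radius,
            "elements": [e.to_dict() for e in self.elements],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def residues_table(self) -> pd.DataFrame:
        """Element -> nearby-residue table (one row per element)."""
        rows = []
        for e in self.elements:
            rows.append({
                "element_type": e.type,
                "centroid_x": round(float(e.centroid[0]), 3),
                "centroid_y": round(float(e.centroid[1]), 3),
                "centroid_z": round(float(e.centroid[2]), 3),
                "radius": round(float(e.radius), 3),
                "support": e.support,
                "residues_within_5A": ", ".join(e.residues),
            })
        return pd.DataFrame(rows)


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def annotate_residues(receptor: Structure, position: np.ndarray,
                      radius: float = 5.0) -> list[str]:
    """Residues with any atom within *radius* Å of *position*.

    Returned as one-letter code + resid (``A192``) for standard residues,
    ``resname+resid`` otherwise, ordered by (chain, resid).
    """
    position = np.asarray(position, dtype=float)
    found: dict[tuple, str] = {}
    for a in receptor.atoms:
        if np.linalg.norm(a.coord - position) <= radius:
            one = _THREE_TO_ONE.get(a.resname.upper(), a.resname)
            found[(a.chain, a.resid)] = f"{one}{a.resid}"
    return [found[k] for k in sorted(found)]


def build_consensus(pose_set: PoseSet, receptor: Structure | None,
                    rules: FeatureRules | None = None,
                    size_weight: float = 1.0,
                    min_support: int | None = None,
                    annotation_radius: float = 5.0,
                    k_range=None,
                    representatives: dict[str, str] | None = None
                    ) -> ConsensusModel:
    """Build the consensus interaction model from one pose per ligand.

    When *representatives* is None the poses are first clustered per
    ligand at 2 Å and the representative of the largest cluster is used.
    Elements with support below *min_support* (default 10% of ligands,
    at least 1) are dropped; survivors are annotated with receptor
    residues within *annotation_radius*.
    """
    if len(pose_set) == 0:
        raise ValueError("no poses")
    if representatives is None:
        from .clustering import pose_cluster
        _, representatives = pose_cluster(pose_set)
    reps = pose_set.subset(representatives)
    ligands = reps.ligand_ids()
    n_ligands = len(ligands)
    if min_support is None:
        min_support = max(1, int(np.ceil(0.10 * n_ligands)))

    features: list[PharmacophoreFeature] = []
    for pose in reps:
        features.extend(extract_features(pose, rules))

    elements: list[ConsensusElement] = []
    for ftype in FEATURE_TYPES:
        group = [f for f in features if f.type == ftype]
        if not group:
            continue
        positions = np.array([f.position for f in group])
        radii = np.array([f.radius for f in group])
        if len(group) == 1:
            medoids, assignment = [0], np.zeros(1, dtype=int)
        else:
            dist = feature_distance_matrix(positions, radii, size_weight)
            k = choose_k(dist, k_range)
            medoids, assignment, _ = pam_kmedoids(dist, k)
        for m in medoids:
            member_idx = np.nonzero(np.asarray(assignment) == m)[0]
            members = [group[i] for i in member_idx]
            contributing = sorted({f.ligand_id for f in members})
            centroid = positions[member_idx].mean(axis=0)
            spread = float(np.sqrt(np.mean(
                np.sum((positions[member_idx] - centroid) ** 2, axis=1))))
            elements.append(ConsensusElement(
                type=ftype, centroid=centroid,
                radius=float(radii[m]) + spread,
                support=len(contributing), ligand_ids=contributing,
            ))

    elements = [e for e in elements if e.support >= min_support]
    if not elements:
        warnings.warn("consensus model is empty (min_support too high)",
                      stacklevel=2)
    elements.sort(key=lambda e: (-e.support, e.type))
    if receptor is not None:
        for e in elements:
            e.residues = annotate_residues(receptor, e.centroid,
                                           annotation_radius)
    return ConsensusModel(elements=elements, n_ligands=n_ligands,
                          min_support=min_support,
                          annotation_radius=annotation_radius)


def compare_models(model_a: ConsensusModel, model_b: ConsensusModel,
                   match_radius: float = 2.0) -> pd.DataFrame:
    """Greedy same-type nearest-centroid matching of two models.

    Returns a tidy report with one row per matched pair or unmatched
    element (``status`` in matched/only_a/only_b).
    """
    rows = []
    used_b: set[int] = set()
    for ftype in FEATURE_TYPES:
        ia = [i for i, e in enumerate(model_a.elements) if e.type == ftype]
        ib = [i for i, e in enumerate(model_b.elements) if e.type == ftype]
        pairs = []
        for i in ia:
            for j in ib:
                d = float(np.linalg.norm(
                    model_a.elements[i].centroid
                    - model_b.elements[j].centroid))
                if d <= match_radius:
                    pairs.append((d, i, j))
        pairs.sort()
        matched_a: set[int] = set()
        for d, i, j in pairs:
            if i in matched_a or j in used_b:
                continue
            matched_a.add(i)
            used_b.add(j)
            rows.append({"type": ftype, "status": "matched",
                         "index_a": i, "index_b": j,
                         "centroid_shift": round(d, 6)})
        for i in ia:
            if i not in matched_a:
                rows.append({"type": ftype, "status": "only_a",
                             "index_a": i, "index_b": None,
                             "centroid_shift": None})
        for j in ib:
            if j not in used_b:
                rows.append({"type": ftype, "status": "only_b",
                             "index_a": None, "index_b": j,
                             "centroid_shift": None})
    return pd.DataFrame(rows,
                        columns=["type", "status", "index_a", "index_b",
                                 "centroid_shift"])
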