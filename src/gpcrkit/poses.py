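"""Ligand pose ensembles and SDF I/O.

A pose is a small molecule conformation: elements, coordinates, formal
charges, aromatic flags and a bond list, plus ligand/pose identifiers and
an optional pKi.  Multi-record SDF files are read and written through
RDKit (one record per pose; ligand id in the title, pose id and pKi in
data tags).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LigandPose", "PoseSet", "read_sdf", "write_sdf"]


@dataclass
class LigandPose:
    ligand_id: str
    pose_id: str
    elements: list[str]
    coords: np.ndarray                      # (n, 3) Å
    bonds: list[tuple[int, int, int]]       # (i, j, order); order 12 = aromatic
    charges: list[int] = field(default_factory=list)
    aromatic: list[bool] = field(default_factory=list)
    pki: float | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise ValueError("coords shape mismatch")
        if not self.charges:
            self.charges = [0] * n
        if not self.aromatic:
            self.aromatic = [False] * n
        if len(self.charges) != n or len(self.aromatic) != n:
            raise ValueError("per-atom field length mismatch")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"dangling bond ({i}, {j})")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def translated(self, shift) -> "LigandPose":
        return LigandPose(
            ligand_id=self.ligand_id, pose_id=self.pose_id,
            elements=list(self.elements),
            coords=self.coords + np.asarray(shift, dtype=float),
            bonds=list(self.bonds), charges=list(self.charges),
            aromatic=list(self.aromatic), pki=self.pki,
        )

    def transformed(self, rotation, translation) -> "LigandPose":
        rotation = np.asarray(rotation, dtype=float)
        return LigandPose(
            ligand_id=self.ligand_id, pose_id=self.pose_id,
            elements=list(self.elements),
            coords=self.coords @ rotation.T + np.asarray(translation),
            bonds=list(self.bonds), charges=list(self.charges),
            aromatic=list(self.aromatic), pki=self.pki,
        )


@dataclass
class PoseSet:
    poses: list[LigandPose] = field(default_factory=list)

    def __len__(self):
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)

    def ligand_ids(self) -> list[str]:
        out = []
        for p in self.poses:
            if p.ligand_id not in out:
                out.append(p.ligand_id)
        return out

    def by_ligand(self) -> dict[str, list[LigandPose]]:
        out: dict[str, list[LigandPose]] = {}
        for p in self.poses:
            out.setdefault(p.ligand_id, []).append(p)
        return out

    def filter_pki(self, lo: float, hi: float) -> "PoseSet":
        """Keep ligands whose pKi lies in [lo, hi]; untagged ligands kept."""
        kept = [p for p in self.poses
                if p.pki is None or lo <= p.pki <= hi]
        return PoseSet(poses=kept)

    def subset(self, ligand_to_pose: dict[str, str]) -> "PoseSet":
        """One chosen pose per ligand (e.g. representatives)."""
        wanted = set(ligand_to_pose.items())
        return PoseSet(poses=[p for p in self.poses
                              if (p.ligand_id, p.pose_id) in wanted])


# ---------------------------------------------------------------------------
# SDF I/O via RDKit
# ---------------------------------------------------------------------------

_AROMATIC_ORDER = 12  # RDKit/SDF convention for aromatic bonds in V2000


def _require_rdkit():
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SDF I/O requires rdkit") from exc
    return Chem


def write_sdf(pose_set: PoseSet, path) -> None:
    Chem = _require_rdkit()
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for pose in pose_set:
            mol = Chem.RWMol()
            for el, q in zip(pose.elements, pose.charges):
                atom = Chem.Atom(el)
                atom.SetFormalCharge(int(q))
                mol.AddAtom(atom)
            for i, j, order in pose.bonds:
                if order == _AROMATIC_ORDER:
                    bt = Chem.BondType.AROMATIC
                else:
                    bt = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                          3: Chem.BondType.TRIPLE}[order]
                mol.AddBond(int(i), int(j), bt)
            for idx, flag in enumerate(pose.aromatic):
                mol.GetAtomWithIdx(idx).SetIsAromatic(bool(flag))
            conf = Chem.Conformer(pose.n_atoms)
            for idx, (x, y, z) in enumerate(pose.coords):
                conf.SetAtomPosition(idx, Point3D(float(x), float(y),
                                                  float(z)))
            mol.AddConformer(conf)
            out = mol.GetMol()
            Chem.SanitizeMol(
                out, Chem.SanitizeFlags.SANITIZE_ALL
                ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE)
            out.SetProp("_Name", pose.ligand_id)
            out.SetProp("pose_id", pose.pose_id)
            if pose.pki is not None:
                out.SetProp("pKi", f"{pose.pki:.3f}")
            writer.write(out)
    finally:
        writer.close()


def read_sdf(path) -> PoseSet:
    Chem = _require_rdkit()
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    poses: list[LigandPose] = []
    counter: dict[str, int] = {}
    for mol in supplier:
        if mol is None:
            continue
        Chem.SanitizeMol(
            mol, Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE)
        ligand_id = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        if not ligand_id:
            ligand_id = f"MOL{len(counter)}"
        if mol.HasProp("pose_id"):
            pose_id = mol.GetProp("pose_id")
        else:
            counter[ligand_id] = counter.get(ligand_id, 0)
            pose_id = f"p{counter[ligand_id]}"
            counter[ligand_id] += 1
        pki = float(mol.GetProp("pKi")) if mol.HasProp("pKi") else None
        conf = mol.GetConformer()
        coords = np.array([[conf.GetAtomPosition(i).x,
                            conf.GetAtomPosition(i).y,
                            conf.GetAtomPosition(i).z]
                           for i in range(mol.GetNumAtoms())])
        bonds = []
        for b in mol.GetBonds():
            if b.GetIsAromatic():
                order = _AROMATIC_ORDER
            else:
                order = int(round(b.GetBondTypeAsDouble()))
            bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        poses.append(LigandPose(
            ligand_id=ligand_id, pose_id=pose_id,
            elements=[a.GetSymbol() for a in mol.GetAtoms()],
            coords=coords, bonds=bonds,
            charges=[a.GetFormalCharge() for a in mol.GetAtoms()],
            aromatic=[a.GetIsAromatic() for a in mol.GetAtoms()],
            pki=pki,
        ))
    return PoseSet(poses=poses)
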