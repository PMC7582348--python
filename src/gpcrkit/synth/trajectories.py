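"""Trajectory generators with planted ground truth.

Two fixtures: (a) a TM bundle whose helices rotate about their own axes
on a per-frame schedule, optionally with whole-body rigid motion and
Gaussian coordinate noise; (b) a receptor-ligand complex where the
ligand chain approaches on a scheduled center-of-mass distance and named
atom pairs are planted at contact distances in chosen frames.
All generators are bitwise deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..geometry import TMSegmentSet, helix_axis
from ..structure import Structure, Trajectory

__all__ = [
    "RotationSchedule",
    "ContactPlant",
    "PLANT_DISTANCES",
    "make_rotated_trajectory",
    "make_complex_trajectory",
    "random_rigid_transform",
]

#: planted pair distance per interaction kind (safely inside the
#: detector cutoffs of 3.5 / 4.0 / 3.9 Å)
PLANT_DISTANCES = {"hbond": 2.9, "saltbridge": 3.0, "hydrophobic": 3.6}
#: clearance beyond the cutoff for frames where a plant is absent
_ABSENT_CLEARANCE = 1.0
_CUTOFFS = {"hbond": 3.5, "saltbridge": 4.0, "hydrophobic": 3.9}


@dataclass
class RotationSchedule:
    """frame index -> {TM name -> planted rotation (degrees)}."""

    n_frames: int
    angles: dict[int, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        frame0 = self.angles.get(0, {})
        if any(abs(v) > 1e-12 for v in frame0.values()):
            raise ValueError("frame 0 is the reference and must map to 0°")
        for f in self.angles:
            if not 0 <= f < self.n_frames:
                raise ValueError(f"frame {f} outside 0..{self.n_frames - 1}")

    def angle(self, frame: int, tm: str) -> float:
        return self.angles.get(frame, {}).get(tm, 0.0)

    def tm_names(self) -> set[str]:
        names: set[str] = set()
        for mapping in self.angles.values():
            names.update(mapping)
        return names


def _rodrigues(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def random_rigid_transform(rng: np.random.Generator,
                           max_translation: float = 20.0):
    """Uniformly random proper rotation plus a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.uniform(-max_translation, max_translation, size=3)
    return rot, trans


def make_rotated_trajectory(bundle: Structure, segments: TMSegmentSet,
                            schedule: RotationSchedule,
                            noise_sd: float = 0.0,
                            global_motion=None,
                            seed: int = 0,
                            noisy_reference: bool = False):
    """Rotate each TM about its own fitted axis per the schedule.

    *global_motion* may be None, ``"random"`` (a fresh random rigid
    transform per frame, frame 0 untouched) or an explicit list of
    ``(rotation, translation)`` per frame.  Gaussian noise of sd
    *noise_sd* Å is added independently per coordinate; the reference
    frame 0 stays noise-free unless *noisy_reference* is set (it stands
    in for the minimized starting structure the analyses reference).
    Returns ``(trajectory, truth)`` where truth is a tidy frame × TM
    table of the planted angles.
    """
    unknown = schedule.tm_names() - set(segments.names())
    if unknown:
        raise ValueError(f"schedule references unknown TMs: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    base = bundle.coords
    n_frames = schedule.n_frames

    seg_atoms: dict[str, np.ndarray] = {}
    seg_axes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for seg in segments:
        lo, hi = seg.resid_range(segments.include_extensions)
        idx = np.array([i for i, a in enumerate(bundle.atoms)
                        if a.chain == seg.chain and lo <= a.resid <= hi])
        ca = np.array([i for i in idx if bundle.atoms[i].name == "CA"])
        seg_atoms[seg.name] = idx
        seg_axes[seg.name] = helix_axis(base[ca])

    if global_motion == "random":
        transforms = [None] + [random_rigid_transform(rng)
                               for _ in range(n_frames - 1)]
    elif global_motion is None:
        transforms = [None] * n_frames
    else:
        transforms = list(global_motion)
        if len(transforms) != n_frames:
            raise ValueError("global_motion length must equal n_frames")

    frames = []
    truth_rows = []
    for f in range(n_frames):
        coords = base.copy()
        for seg in segments:
            ang = schedule.angle(f, seg.name)
            truth_rows.append({"frame": f, "tm": seg.name,
                               "angle_deg": float(ang)})
            if abs(ang) < 1e-12:
                continue
            axis, centroid = seg_axes[seg.name]
            rot = _rodrigues(axis, ang)
            idx = seg_atoms[seg.name]
            coords[idx] = (coords[idx] - centroid) @ rot.T + centroid
        if transforms[f] is not None:
            rot, trans = transforms[f]
            coords = coords @ rot.T + trans
        if noise_sd > 0 and (f > 0 or noisy_reference):
            coords = coords + rng.normal(0.0, noise_sd, size=coords.shape)
        frames.append(coords)
    traj = Trajectory(topology=bundle.copy(), frames=frames)
    truth = pd.DataFrame(truth_rows)
    return traj, truth


@dataclass(frozen=True)
class ContactPlant:
    """One planted interaction between a receptor atom and a ligand atom."""

    receptor_atom: tuple[str, int, str]   # (chain, resid, atom name)
    ligand_atom: tuple[str, int, str]
    kind: str                             # hbond | saltbridge | hydrophobic
    frames: frozenset = frozenset()

    def __post_init__(self):
        if self.kind not in PLANT_DISTANCES:
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        object.__setattr__(self, "frames", frozenset(self.frames))


def make_complex_trajectory(receptor: Structure, ligand_chain: Structure,
                            approach: list[float],
                            plants: list[ContactPlant] = (),
                            seed: int = 0,
                            direction=None):
    """Receptor + rigid ligand chain on a scheduled COM-distance approach.

    Per frame, the ligand is placed so the mass-weighted COM distance to
    the receptor equals the scheduled value; planted atom pairs are then
    realized at kind-specific distances in their frames and pushed
    ≥ cutoff + 1 Å apart elsewhere, with the remaining ligand atoms
    compensating so the COM distance stays exact.  Returns
    ``(trajectory, truth)`` with truth columns
    ``frame, kind, receptor_atom, ligand_atom, present``.
    """
    approach = [float(d) for d in approach]
    if any(d <= 0 for d in approach):
        raise ValueError("approach distances must be positive")
    plants = list(plants)
    # conflicting plants: same ligand atom scheduled in overlapping frames
    for i in range(len(plants)):
        for j in range(i + 1, len(plants)):
            if plants[i].ligand_atom == plants[j].ligand_atom and \
                    plants[i].frames & plants[j].frames:
                raise ValueError(
                    f"conflicting plants for ligand atom "
                    f"{plants[i].ligand_atom}")

    # seed kept for interface symmetry; the construction is deterministic
    del seed
    if direction is None:
        direction = np.array([1.0, 0.0, 0.0])
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)

    rec_coords = receptor.coords
    rec_masses = receptor.masses
    rec_com = np.average(rec_coords, axis=0, weights=rec_masses)
    lig_coords0 = ligand_chain.coords
    lig_masses = ligand_chain.masses
    lig_com0 = np.average(lig_coords0, axis=0, weights=lig_masses)

    rec_index = {(a.chain, a.resid, a.name): i
                 for i, a in enumerate(receptor.atoms)}
    lig_index = {(a.chain, a.resid, a.name): i
                 for i, a in enumerate(ligand_chain.atoms)}
    for plant in plants:
        if plant.receptor_atom not in rec_index:
            raise KeyError(f"receptor atom {plant.receptor_atom} not found")
        if plant.ligand_atom not in lig_index:
            raise KeyError(f"ligand atom {plant.ligand_atom} not found")

    # approach direction for each planted pair: outward from the receptor
    # residue's CA through the named atom, so the placed ligand atom does
    # not collide with neighbouring side-chain atoms
    plant_dirs: dict[tuple, np.ndarray] = {}
    for plant in plants:
        ri = rec_index[plant.receptor_atom]
        chain, resid, name = plant.receptor_atom
        u = None
        if name != "CA" and (chain, resid, "CA") in rec_index:
            ca = rec_coords[rec_index[(chain, resid, "CA")]]
            u = rec_coords[ri] - ca
        if u is None or np.linalg.norm(u) < 1e-6:
            u = rec_coords[ri] - rec_com
        plant_dirs[plant.receptor_atom] = u / np.linalg.norm(u)

    frames = []
    truth_rows = []
    for f, target_d in enumerate(approach):
        lig = lig_coords0 - lig_com0 + rec_com + direction * target_d
        planted_idx: set[int] = set()
        for plant in plants:
            li = lig_index[plant.ligand_atom]
            ri = rec_index[plant.receptor_atom]
            present = f in plant.frames
            u = plant_dirs[plant.receptor_atom]
            if present:
                lig[li] = rec_coords[ri] + u * PLANT_DISTANCES[plant.kind]
                planted_idx.add(li)
            else:
                min_d = _CUTOFFS[plant.kind] + _ABSENT_CLEARANCE
                if np.linalg.norm(lig[li] - rec_coords[ri]) < min_d + 0.5:
                    lig[li] = rec_coords[ri] + u * (min_d + 0.5)
                    planted_idx.add(li)
            truth_rows.append({
                "frame": f, "kind": plant.kind,
                "receptor_atom": ":".join(map(str, plant.receptor_atom)),
                "ligand_atom": ":".join(map(str, plant.ligand_atom)),
                "present": present,
            })
            if plant.kind == "saltbridge":
                # an N(+)...O(-) pair at 3.0 Å is also a donor-acceptor
                # contact, so the ground truth carries the implied H-bond
                truth_rows.append({
                    "frame": f, "kind": "hbond",
                    "receptor_atom": ":".join(map(str, plant.receptor_atom)),
                    "ligand_atom": ":".join(map(str, plant.ligand_atom)),
                    "present": present,
                })
        # restore the exact scheduled COM using the unplanted atoms
        free = np.array([i for i in range(len(lig)) if i not in planted_idx])
        if planted_idx and len(free):
            target_com = rec_com + direction * target_d
            current_com = np.average(lig, axis=0, weights=lig_masses)
            total_m = lig_masses.sum()
            free_m = lig_masses[free].sum()
            lig[free] += (target_com - current_com) * (total_m / free_m)
        frames.append(np.vstack([rec_coords, lig]))

    atoms = []
    serial = 1
    for a in list(receptor.atoms) + list(ligand_chain.atoms):
        atoms.append(type(a)(serial=serial, name=a.name, resname=a.resname,
                             chain=a.chain, resid=a.resid,
                             coord=a.coord.copy(), element=a.element,
                             het=a.het))
        serial += 1
    topology = Structure(atoms=atoms)
    traj = Trajectory(topology=topology, frames=frames)
    truth = pd.DataFrame(
        truth_rows, columns=["frame", "kind", "receptor_atom",
                             "ligand_atom", "present"])
    return traj, truth
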