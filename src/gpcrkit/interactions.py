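"""Hydrogen-bond, hydrophobic-contact and salt-bridge detection.

Distance-criterion detectors in the style of the classic contact-analysis
tools: donors/acceptors and charged groups are assigned from residue and
atom names (structures rarely carry hydrogens), cutoffs are configurable,
and results are aggregated into per-frame records and presence
time-tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure import Selection, Structure, Trajectory, select

__all__ = [
    "InteractionCriteria",
    "InteractionRecord",
    "find_hbonds",
    "find_hydrophobic",
    "find_salt_bridges",
    "arginine_cage_state",
    "contact_timetable",
    "records_to_dataframe",
]

# Name-inferred hydrogen-bond capability for the standard residues.
_DONOR_NAMES = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "TRP": {"NE1"}, "HIS": {"ND1", "NE2"}, "CYS": set(),
}
_ACCEPTOR_N_NAMES = {
    "HIS": {"ND1", "NE2"},
}
_NEGATIVE_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
_POSITIVE_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NH1", "NH2", "NE"},
}
_HIS_POSITIVE = {"ND1", "NE2"}

_STANDARD_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Carbons with a nitrogen/oxygen neighbour one bond away, per residue;
# these are excluded from hydrophobic contacts.  Backbone C and CA are
# always polar (bonded to O and N respectively).
_POLAR_CARBONS = {
    "SER": {"CB"}, "THR": {"CB"}, "ASP": {"CG"}, "GLU": {"CD"},
    "ASN": {"CG"}, "GLN": {"CD"}, "ARG": {"CD", "CZ"}, "LYS": {"CE"},
    "TYR": {"CZ"}, "TRP": {"CD1", "CE2"}, "HIS": {"CG", "CD2", "CE1"},
    "PRO": {"CD"},
}


@dataclass
class InteractionCriteria:
    """Cutoffs and group definitions for the three detectors."""

    hbond_da_max: float = 3.5        # donor-acceptor heavy-atom distance, Å
    hbond_angle_min: float = 120.0   # D-H...A, applied only with explicit H
    hydrophobic_cc_max: float = 3.9  # carbon-carbon distance, Å
    saltbridge_max: float = 4.0      # charged-atom pair distance, Å
    his_positive: bool = False       # count His ND1/NE2 as positive
    include_terminal_charges: bool = True  # N-term N positive, OXT negative

    def __post_init__(self):
        for name in ("hbond_da_max", "hydrophobic_cc_max", "saltbridge_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class InteractionRecord:
    kind: str        # hbond | hydrophobic | saltbridge
    frame: int
    atom_i: str
    atom_j: str
    residue_i: str
    residue_j: str
    distance: float
    angle: float | None = None

    def residue_pair(self) -> tuple[str, str]:
        return (self.residue_i, self.residue_j)


def _atom_sort_key(atom):
    return (atom.chain, atom.resid, atom.name)


def _first_resids(structure: Structure) -> dict[str, int]:
    firsts: dict[str, int] = {}
    for a in structure.atoms:
        firsts.setdefault(a.chain, a.resid)
        firsts[a.chain] = min(firsts[a.chain], a.resid)
    return firsts


def _is_donor(atom, structure_firsts) -> bool:
    if atom.element.upper() not in ("N", "O"):
        return False
    res = atom.resname.upper()
    if res in _STANDARD_RESNAMES:
        if atom.name == "N":
            return res != "PRO"
        return atom.name in _DONOR_NAMES.get(res, set())
    # unknown chemistry (ligands, CG beads): any N/O may carry an H
    return True

def _is_acceptor(atom, criteria: InteractionCriteria) -> bool:
    elem = atom.element.upper()
    if elem not in ("N", "O"):
        return False
    res = atom.resname.upper()
    if _is_positive(atom, criteria, firsts=None):
        return False
    if elem == "O":
        return True
    if res in _STANDARD_RESNAMES:
        return atom.name in _ACCEPTOR_N_NAMES.get(res, set())
    return True

def _is_positive(atom, criteria: InteractionCriteria, firsts) -> bool:
    res = atom.resname.upper()
    if atom.name in _POSITIVE_ATOMS.get(res, set()):
        return True
    if criteria.his_positive and res == "HIS" and atom.name in _HIS_POSITIVE:
        return True
    if (criteria.include_terminal_charges and firsts is not None
            and atom.name == "N" and res in _STANDARD_RESNAMES
            and firsts.get(atom.chain) == atom.resid):
        return True
    return False

def _is_negative(atom, criteria: InteractionCriteria) -> bool:
    res = atom.resname.upper()
    if atom.name in _NEGATIVE_ATOMS.get(res, set()):
        return True
    if criteria.include_terminal_charges and atom.name == "OXT":
        return True
    return False

def _is_nonpolar_carbon(atom) -> bool:
    if atom.element.upper() != "C":
        return False
    if atom.name in ("C", "CA"):
        return False
    res = atom.resname.upper()
    if res in _STANDARD_RESNAMES:
        return atom.name not in _POLAR_CARBONS.get(res, set())
    return True


def _resolve_groups(structure: Structure, coords, group_a, group_b):
    idx_a = group_a if not isinstance(group_a, (str, Selection)) \
        else select(Trajectory(topology=structure, frames=[coords]), group_a)
    idx_b = group_b if not isinstance(group_b, (str, Selection)) \
        else select(Trajectory(topology=structure, frames=[coords]), group_b)
    return list(idx_a), list(idx_b)


def _make_record(kind, frame, atom_a, atom_b, dist, coords_a=None,
                 angle=None) -> InteractionRecord:
    a, b = atom_a, atom_b
    if _atom_sort_key(b) < _atom_sort_key(a):
        a, b = b, a
    return InteractionRecord(
        kind=kind, frame=frame,
        atom_i=a.atom_id(), atom_j=b.atom_id(),
        residue_i=a.residue_id(), residue_j=b.residue_id(),
        distance=float(dist), angle=angle,
    )


def _explicit_hydrogens(structure: Structure, coords, donor_idx: int):
    """Indices of H atoms covalently close (< 1.25 Å) to the donor."""
    donor = structure.atoms[donor_idx]
    out = []
    for i, a in enumerate(structure.atoms):
        if a.element.upper() != "H" or a.chain != donor.chain \
                or a.resid != donor.resid:
            continue
        if np.linalg.norm(coords[i] - coords[donor_idx]) < 1.25:
            out.append(i)
    return out


def find_hbonds(structure: Structure, coords: np.ndarray, group_a, group_b,
                criteria: InteractionCriteria | None = None,
                frame: int = 0) -> list[InteractionRecord]:
    """Hydrogen bonds between two atom groups in one frame.

    A pair is reported when a donor N/O and an acceptor N/O are within
    ``hbond_da_max``; if the donor has explicit hydrogens, the best
    D-H...A angle must also exceed ``hbond_angle_min``.
    """
    criteria = criteria or InteractionCriteria()
    coords = np.asarray(coords, dtype=float)
    idx_a, idx_b = _resolve_groups(structure, coords, group_a, group_b)
    firsts = _first_resids(structure)
    records: dict[tuple, InteractionRecord] = {}
    for side_d, side_a in ((idx_a, idx_b), (idx_b, idx_a)):
        donors = [i for i in side_d if _is_donor(structure.atoms[i], firsts)]
        acceptors = [i for i in side_a
                     if _is_acceptor(structure.atoms[i], criteria)]
        if not donors or not acceptors:
            continue
        d = cdist(coords[donors], coords[acceptors])
        for di, ai in zip(*np.nonzero(d <= criteria.hbond_da_max)):
            i, j = donors[di], acceptors[ai]
            da, aa = structure.atoms[i], structure.atoms[j]
            if (da.chain, da.resid) == (aa.chain, aa.resid):
                continue
            angle = None
            hydrogens = _explicit_hydrogens(structure, coords, i)
            if hydrogens:
                angles = [_dha_angle(coords[i], coords[h], coords[j])
                          for h in hydrogens]
                angle = max(angles)
                if angle < criteria.hbond_angle_min:
                    continue
            key = tuple(sorted((i, j)))
            rec = _make_record("hbond", frame, da, aa, d[di, ai], angle=angle)
            if key not in records or rec.distance < records[key].distance:
                records[key] = rec
    return sorted(records.values(),
                  key=lambda r: (r.residue_i, r.residue_j, r.atom_i, r.atom_j))


def _dha_angle(d, h, a) -> float:
    v1 = np.asarray(d) - np.asarray(h)
    v2 = np.asarray(a) - np.asarray(h)
    cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def find_hydrophobic(structure: Structure, coords: np.ndarray, group_a,
                     group_b, criteria: InteractionCriteria | None = None,
                     frame: int = 0) -> list[InteractionRecord]:
    """Nonpolar carbon-carbon contacts, one record per residue pair
    (minimum distance kept)."""
    criteria = criteria or InteractionCriteria()
    coords = np.asarray(coords, dtype=float)
    idx_a, idx_b = _resolve_groups(structure, coords, group_a, group_b)
    carb_a = [i for i in idx_a if _is_nonpolar_carbon(structure.atoms[i])]
    carb_b = [i for i in idx_b if _is_nonpolar_carbon(structure.atoms[i])]
    return _pairwise_residue_records(
        structure, coords, carb_a, carb_b, criteria.hydrophobic_cc_max,
        "hydrophobic", frame)


def find_salt_bridges(structure: Structure, coords: np.ndarray, group_a,
                      group_b, criteria: InteractionCriteria | None = None,
                      frame: int = 0) -> list[InteractionRecord]:
    """Oppositely charged atom pairs within ``saltbridge_max``, one record
    per residue pair (minimum distance kept)."""
    criteria = criteria or InteractionCriteria()
    coords = np.asarray(coords, dtype=float)
    idx_a, idx_b = _resolve_groups(structure, coords, group_a, group_b)
    firsts = _first_resids(structure)
    records: dict[tuple, InteractionRecord] = {}
    for side1, side2 in ((idx_a, idx_b), (idx_b, idx_a)):
        neg = [i for i in side1
               if _is_negative(structure.atoms[i], criteria)]
        pos = [i for i in side2
               if _is_positive(structure.atoms[i], criteria, firsts)]
        if not neg or not pos:
            continue
        d = cdist(coords[neg], coords[pos])
        for ni, pi in zip(*np.nonzero(d <= criteria.saltbridge_max)):
            i, j = neg[ni], pos[pi]
            na, pa = structure.atoms[i], structure.atoms[j]
            if (na.chain, na.resid) == (pa.chain, pa.resid):
                continue
            rec = _make_record("saltbridge", frame, na, pa, d[ni, pi])
            key = (rec.residue_i, rec.residue_j)
            if key not in records or rec.distance < records[key].distance:
                records[key] = rec
    return sorted(records.values(),
                  key=lambda r: (r.residue_i, r.residue_j))


def _pairwise_residue_records(structure, coords, idx_a, idx_b, cutoff, kind,
                              frame) -> list[InteractionRecord]:
    if not idx_a or not idx_b:
        return []
    d = cdist(coords[idx_a], coords[idx_b])
    records: dict[tuple, InteractionRecord] = {}
    for ia, ib in zip(*np.nonzero(d <= cutoff)):
        i, j = idx_a[ia], idx_b[ib]
        aa, ab = structure.atoms[i], structure.atoms[j]
        if (aa.chain, aa.resid) == (ab.chain, ab.resid):
            continue
        rec = _make_record(kind, frame, aa, ab, d[ia, ib])
        key = (rec.residue_i, rec.residue_j)
        if key not in records or rec.distance < records[key].distance:
            records[key] = rec
    return sorted(records.values(), key=lambda r: (r.residue_i, r.residue_j))


# ---------------------------------------------------------------------------
# Trajectory-level tables
# ---------------------------------------------------------------------------

def arginine_cage_state(traj: Trajectory, d_res: tuple[str, int] = ("R", 148),
                        r_res: tuple[str, int] = ("R", 149),
                        criteria: InteractionCriteria | None = None,
                        stride: int = 1) -> pd.DataFrame:
    """Per-frame presence of the Asp-Arg ionic lock between two residues.

    Returns a DataFrame with columns ``frame, time_ns, present``; formatted
    as an X/blank presence table by :func:`presence_table`.
    """
    criteria = criteria or InteractionCriteria()
    d_chain, d_resid = d_res
    r_chain, r_resid = r_res
    d_atoms = [a for a in traj.topology.atoms
               if a.chain == d_chain and a.resid == d_resid]
    r_atoms = [a for a in traj.topology.atoms
               if a.chain == r_chain and a.resid == r_resid]
    if not d_atoms or not r_atoms:
        raise ValueError(
            f"arginine cage residues {d_res} / {r_res} not found")
    if d_atoms[0].resname.upper() not in ("ASP", "GLU"):
        warnings.warn(
            f"residue {d_res} is {d_atoms[0].resname}, expected Asp/Glu",
            stacklevel=2)
    if r_atoms[0].resname.upper() not in ("ARG", "LYS"):
        warnings.warn(
            f"residue {r_res} is {r_atoms[0].resname}, expected Arg/Lys",
            stacklevel=2)
    idx_d = [i for i, a in enumerate(traj.topology.atoms)
             if a.chain == d_chain and a.resid == d_resid]
    idx_r = [i for i, a in enumerate(traj.topology.atoms)
             if a.chain == r_chain and a.resid == r_resid]
    rows = []
    for f in range(0, traj.n_frames, max(1, stride)):
        recs = find_salt_bridges(traj.topology, traj.frames[f], idx_d, idx_r,
                                 criteria, frame=f)
        t = traj.times[f] if traj.times is not None else float(f)
        rows.append({"frame": f, "time_ns": t, "present": bool(recs)})
    return pd.DataFrame(rows)


def contact_timetable(traj: Trajectory, group_a, group_b,
                      criteria: InteractionCriteria | None = None,
                      stride: int = 1):
    """Union of the three detectors over sampled frames.

    Returns ``(records, presence, counts)``: the full record list, a wide
    frame × named-interaction boolean table (keys ``kind:resA-resB``) and
    per-frame counts by kind.
    """
    criteria = criteria or InteractionCriteria()
    idx_a = select(traj, group_a) if isinstance(group_a, (str, Selection)) \
        else list(group_a)
    idx_b = select(traj, group_b) if isinstance(group_b, (str, Selection)) \
        else list(group_b)
    all_records: list[InteractionRecord] = []
    frames = list(range(0, traj.n_frames, max(1, stride)))
    presence_rows = []
    count_rows = []
    for f in frames:
        coords = traj.frames[f]
        frame_recs: list[InteractionRecord] = []
        for finder in (find_hbonds, find_hydrophobic, find_salt_bridges):
            frame_recs.extend(
                finder(traj.topology, coords, idx_a, idx_b, criteria,
                       frame=f))
        all_records.extend(frame_recs)
        t = traj.times[f] if traj.times is not None else float(f)
        row = {"frame": f, "time_ns": t}
        for rec in frame_recs:
            row[f"{rec.kind}:{rec.residue_i}-{rec.residue_j}"] = True
        presence_rows.append(row)
        counts = {"frame": f, "time_ns": t,
                  "hbond": 0, "hydrophobic": 0, "saltbridge": 0}
        for rec in frame_recs:
            counts[rec.kind] += 1
        counts["total"] = len(frame_recs)
        count_rows.append(counts)
    presence = pd.DataFrame(presence_rows).fillna(False).infer_objects(
        copy=False)
    meta = ["frame", "time_ns"]
    presence = presence[meta + sorted(c for c in presence.columns
                                      if c not in meta)]
    counts = pd.DataFrame(count_rows)
    return all_records, presence, counts


def presence_table(presence: pd.DataFrame) -> pd.DataFrame:
    """X/blank rendering of a boolean presence table (rows = time frames)."""
    out = presence.copy()
    for col in out.columns:
        if col in ("frame", "time_ns"):
            continue
        out[col] = np.where(out[col].astype(bool), "X", "")
    return out


def records_to_dataframe(records) -> pd.DataFrame:
    cols = ["frame", "kind", "atom_i", "atom_j", "residue_i", "residue_j",
            "distance", "angle"]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.__dict__ for r in records])[cols]
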