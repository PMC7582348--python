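"""Ideal helices and multi-helix bundles with known geometry."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..geometry import TMSegment, TMSegmentSet, helix_axis
from ..structure import Atom, Structure

__all__ = ["HelixSpec", "make_ideal_helix", "make_tm_bundle",
           "seven_tm_specs", "seven_tm_bundle", "decorate_residue"]

# Idealized backbone internal coordinates (lengths Å, angles deg).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8
_ALPHA_PHI, _ALPHA_PSI, _OMEGA = -57.0, -47.0, 180.0


@dataclass
class HelixSpec:
    n_res: int
    rise: float = 1.5               # Å per residue (Cα-trace mode)
    twist: float = 100.0            # degrees per residue (Cα-trace mode)
    radius: float = 2.3             # helix radius, Å (Cα-trace mode)
    axis_origin: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    chain: str = "R"
    start_resid: int = 1
    resname: str = "ALA"
    mode: str = "calpha"            # "calpha" or "backbone"
    phi: float = _ALPHA_PHI         # backbone mode dihedrals
    psi: float = _ALPHA_PSI

    def __post_init__(self):
        if self.n_res < 4:
            raise ValueError("n_res must be at least 4")
        self.axis_origin = np.asarray(self.axis_origin, dtype=float)
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        norm = np.linalg.norm(self.axis_direction)
        if abs(norm - 1.0) > 1e-9:
            if norm < 1e-12:
                raise ValueError("axis_direction must be a unit vector")
            self.axis_direction = self.axis_direction / norm
        if self.mode not in ("calpha", "backbone"):
            raise ValueError("mode must be 'calpha' or 'backbone'")


def _orthonormal_frame(axis: np.ndarray):
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def _nerf_place(a, b, c, bond: float, angle_deg: float,
                dihedral_deg: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to a-b-c."""
    angle = np.radians(angle_deg)
    # sign flipped so the resulting torsion matches the IUPAC convention
    dihedral = -np.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(angle),
                        bond * np.sin(angle) * np.cos(dihedral),
                        bond * np.sin(angle) * np.sin(dihedral)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _backbone_coords(n_res: int, phi: float, psi: float):
    """N, CA, C, O per residue from ideal internal coordinates."""
    atoms: list[tuple[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    prev = {"N": n0, "CA": ca0, "C": c0}
    residues = [dict(prev)]
    for _ in range(1, n_res):
        n = _nerf_place(prev["N"], prev["CA"], prev["C"],
                        _B_C_N, _A_CA_C_N, psi)
        ca = _nerf_place(prev["CA"], prev["C"], n,
                         _B_N_CA, _A_C_N_CA, _OMEGA)
        c = _nerf_place(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi)
        prev = {"N": n, "CA": ca, "C": c}
        residues.append(dict(prev))
    # carbonyl O: dihedral N-CA-C-O = psi + 180 (trans to the next N)
    for res in residues:
        res["O"] = _nerf_place(res["N"], res["CA"], res["C"],
                               _B_C_O, _A_CA_C_O, psi + 180.0)
    return residues


def make_ideal_helix(spec: HelixSpec) -> Structure:
    """Build an ideal helix for a :class:`HelixSpec`.

    In ``calpha`` mode Cα atoms are placed parametrically on a helix with
    the requested rise/twist/radius about ``axis_direction``.  In
    ``backbone`` mode an N-CA-C-O backbone is grown from ideal internal
    coordinates with the spec's φ/ψ and then rigidly aligned so its
    principal axis matches ``axis_direction`` (N- to C-terminal).
    """
    e1, e2 = _orthonormal_frame(spec.axis_direction)
    atoms: list[Atom] = []
    serial = 1
    if spec.mode == "calpha":
        for i in range(spec.n_res):
            theta = np.radians(spec.twist * i)
            pos = (spec.axis_origin
                   + spec.axis_direction * (spec.rise * i)
                   + spec.radius * (np.cos(theta) * e1 + np.sin(theta) * e2))
            atoms.append(Atom(serial=serial, name="CA", resname=spec.resname,
                              chain=spec.chain, resid=spec.start_resid + i,
                              coord=pos, element="C"))
            serial += 1
        return Structure(atoms=atoms)

    residues = _backbone_coords(spec.n_res, spec.phi, spec.psi)
    ca = np.array([r["CA"] for r in residues])
    axis, centroid = helix_axis(ca)
    # rotate fitted axis onto the requested direction
    rot = _rotation_between(axis, spec.axis_direction)
    for i, res in enumerate(residues):
        for name in ("N", "CA", "C", "O"):
            pos = rot @ (res[name] - centroid) + spec.axis_origin
            atoms.append(Atom(serial=serial, name=name,
                              resname=spec.resname, chain=spec.chain,
                              resid=spec.start_resid + i, coord=pos,
                              element=name[0]))
            serial += 1
    return Structure(atoms=atoms)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 about any perpendicular axis
        perp = _orthonormal_frame(a)[0]
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def seven_tm_specs(chain: str = "R", circle_radius: float = 11.0,
                   mode: str = "calpha",
                   include_extensions: bool = True) -> list[HelixSpec]:
    """Specs for a 7-helix bundle whose resid ranges follow the default
    TM table (extensions fold the DRY tail into TM3 and 234-235 into TM5)."""
    ranges = [("TM1", 54, 80, None), ("TM2", 90, 110, None),
              ("TM3", 126, 147, (148, 150)), ("TM4", 170, 189, None),
              ("TM5", 213, 233, (234, 235)), ("TM6", 256, 277, None),
              ("TM7", 299, 321, None)]
    specs = []
    for i, (name, lo, hi, ext) in enumerate(ranges):
        build_hi = ext[1] if (ext and include_extensions) else hi
        n_res = build_hi - lo + 1
        angle = 2.0 * np.pi * i / 7.0
        origin = circle_radius * np.array([np.cos(angle), np.sin(angle), 0.0])
        direction = np.array([0.0, 0.0, 1.0 if i % 2 == 0 else -1.0])
        specs.append(HelixSpec(
            n_res=n_res, axis_origin=origin, axis_direction=direction,
            chain=chain, start_resid=lo, mode=mode))
    return specs


def seven_tm_bundle(chain: str = "R", include_extensions: bool = True,
                    mode: str = "calpha") -> tuple[Structure, TMSegmentSet]:
    """The default 7-helix fixture with its canonical segment table."""
    from ..geometry import cxcr3_segments
    specs = seven_tm_specs(chain=chain, mode=mode,
                           include_extensions=include_extensions)
    structure, _ = make_tm_bundle(specs)
    return structure, cxcr3_segments(chain, include_extensions)


def make_tm_bundle(specs: list[HelixSpec],
                   segments: TMSegmentSet | None = None,
                   min_separation: float = 2.0
                   ) -> tuple[Structure, TMSegmentSet]:
    """Assemble helices into one chain and record the segment table.

    Raises if any two helices clash (< *min_separation* Å between atoms
    of different helices).  When *segments* is omitted, each helix i is
    recorded as ``TM{i+1}`` spanning its built residue range.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 helices")
    helices = [make_ideal_helix(s) for s in specs]
    for i in range(len(helices)):
        for j in range(i + 1, len(helices)):
            ci, cj = helices[i].coords, helices[j].coords
            d2 = np.sum((ci[:, None, :] - cj[None, :, :]) ** 2, axis=2)
            if d2.min() < min_separation ** 2:
                raise ValueError(
                    f"helices {i} and {j} clash "
                    f"(min distance {np.sqrt(d2.min()):.2f} Å)")
    atoms: list[Atom] = []
    serial = 1
    for h in helices:
        for a in h.atoms:
            atoms.append(Atom(serial=serial, name=a.name, resname=a.resname,
                              chain=a.chain, resid=a.resid,
                              coord=a.coord.copy(), element=a.element))
            serial += 1
    structure = Structure(atoms=atoms)
    if segments is None:
        segs = []
        for i, s in enumerate(specs):
            segs.append(TMSegment(
                name=f"TM{i + 1}", chain=s.chain, first=s.start_resid,
                last=s.start_resid + s.n_res - 1))
        segments = TMSegmentSet(segments=segs)
    return structure, segments


# Minimal side-chain templates: offsets (Å) from CA along an outward
# direction d (first component) and two perpendicular components.
_SIDECHAINS = {
    "ASP": [("CB", 1.5, 0.3, 0.0), ("CG", 2.8, 0.5, 0.2),
            ("OD1", 3.6, 1.3, 0.3), ("OD2", 3.6, -0.4, 0.6)],
    "GLU": [("CB", 1.5, 0.3, 0.0), ("CG", 2.8, 0.5, 0.2),
            ("CD", 4.0, 0.8, 0.3), ("OE1", 4.8, 1.6, 0.4),
            ("OE2", 4.8, -0.1, 0.7)],
    "ARG": [("CB", 1.5, 0.3, 0.0), ("CG", 2.8, 0.5, 0.2),
            ("CD", 4.0, 0.8, 0.3), ("NE", 5.2, 1.0, 0.4),
            ("CZ", 6.3, 1.2, 0.5), ("NH1", 7.2, 1.9, 0.6),
            ("NH2", 6.8, 0.2, 0.8)],
    "LYS": [("CB", 1.5, 0.3, 0.0), ("CG", 2.8, 0.5, 0.2),
            ("CD", 4.0, 0.8, 0.3), ("CE", 5.2, 1.0, 0.4),
            ("NZ", 6.3, 1.2, 0.5)],
    "SER": [("CB", 1.5, 0.3, 0.0), ("OG", 2.7, 0.6, 0.2)],
    "ASN": [("CB", 1.5, 0.3, 0.0), ("CG", 2.8, 0.5, 0.2),
            ("OD1", 3.6, 1.3, 0.3), ("ND2", 3.6, -0.4, 0.6)],
    "GLN": [("CB", 1.5, 0.3, 0.0), ("CG", 2.8, 0.5, 0.2),
            ("CD", 4.0, 0.8, 0.3), ("OE1", 4.8, 1.6, 0.4),
            ("NE2", 4.8, -0.1, 0.7)],
    "LEU": [("CB", 1.5, 0.3, 0.0), ("CG", 2.8, 0.5, 0.2),
            ("CD1", 3.7, 1.3, 0.3), ("CD2", 3.6, -0.4, 0.6)],
    "VAL": [("CB", 1.5, 0.3, 0.0), ("CG1", 2.7, 1.1, 0.2),
            ("CG2", 2.6, -0.4, 0.5)],
}


def decorate_residue(structure: Structure, chain: str, resid: int,
                     resname: str,
                     direction: np.ndarray | None = None) -> Structure:
    """Return a copy with one residue mutated and given template
    side-chain atoms sticking out along *direction* (default: radially
    away from the structure centroid)."""
    if resname not in _SIDECHAINS:
        raise ValueError(f"no side-chain template for {resname}")
    s = structure.copy()
    ca_idx = None
    for i, a in enumerate(s.atoms):
        if a.chain == chain and a.resid == resid:
            a.resname = resname
            if a.name == "CA":
                ca_idx = i
    if ca_idx is None:
        raise KeyError(f"residue {chain}:{resid} has no CA")
    ca = s.atoms[ca_idx].coord
    if direction is None:
        direction = ca - s.coords.mean(axis=0)
        direction[2] = 0.0
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    p1, p2 = _orthonormal_frame(direction)
    existing = {a.name for a in s.atoms
                if a.chain == chain and a.resid == resid}
    max_serial = max(a.serial for a in s.atoms)
    new_atoms = list(s.atoms)
    insert_at = max(i for i, a in enumerate(s.atoms)
                    if a.chain == chain and a.resid == resid) + 1
    added = []
    for name, d0, d1, d2 in _SIDECHAINS[resname]:
        if name in existing:
            continue
        pos = ca + d0 * direction + d1 * p1 + d2 * p2
        max_serial += 1
        added.append(Atom(serial=max_serial, name=name, resname=resname,
                          chain=chain, resid=resid, coord=pos,
                          element=name[0]))
    new_atoms[insert_at:insert_at] = added
    return Structure(atoms=new_atoms, title=s.title)
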