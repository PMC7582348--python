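"""Structures, multi-frame trajectories, PDB I/O and atom selections.

The on-disk format is plain PDB (``ATOM``/``HETATM`` with optional
``MODEL``/``ENDMDL`` blocks); a multi-MODEL file is read as a trajectory
whose frames share the topology of the first MODEL.  Selections use a
small expression language (``chain R and resid 54-80 and name CA``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Selection",
    "SelectionError",
    "PDBError",
    "read_pdb",
    "write_pdb",
    "select",
    "ATOMIC_MASSES",
]

#: Monoisotopic-ish average masses for COM computations; unknown symbols
#: (coarse-grained bead types and the like) fall back to 1.0.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "FE": 55.845, "ZN": 65.38, "MG": 24.305, "NA": 22.990, "K": 39.098,
    "CA": 40.078, "MN": 54.938, "SE": 78.971,
}

_TWO_LETTER_ELEMENTS = {"CL", "BR", "FE", "ZN", "MG", "NA", "MN", "SE"}


class PDBError(ValueError):
    """Raised for malformed or unsupported PDB content."""


class SelectionError(ValueError):
    """Raised when a selection expression cannot be parsed."""


def mass_of(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), 1.0)


def infer_element(name: str, resname: str = "") -> str:
    """Guess the element from a PDB atom name.

    Protein/nucleic atom names start with the element letter (possibly
    preceded by a digit, as in ``1HB``); a handful of two-letter elements
    are recognised when the name starts with them and the second letter
    is not a typical remoteness label.
    """
    stripped = name.strip()
    stripped = stripped.lstrip("0123456789")
    if not stripped:
        raise PDBError(f"cannot infer element for atom name {name!r}")
    two = stripped[:2].upper()
    # "CA" in a protein residue is an alpha carbon, not calcium; only accept
    # two-letter metals/halogens for non-standard residues.
    if two in _TWO_LETTER_ELEMENTS:
        return two.capitalize()
    return stripped[0].upper()


@dataclass
class Atom:
    """One atom (or coarse-grained bead) of a topology."""

    serial: int
    name: str
    resname: str
    chain: str
    resid: int
    coord: np.ndarray
    element: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0
    het: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError("coord must be a 3-vector")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("coord must be finite")
        if not self.element:
            self.element = infer_element(self.name, self.resname)

    @property
    def mass(self) -> float:
        return mass_of(self.element)

    def atom_id(self) -> str:
        return f"{self.chain}:{self.resname}{self.resid}:{self.name}"

    def residue_id(self) -> str:
        return f"{self.chain}:{self.resname}{self.resid}"


@dataclass
class Structure:
    """An ordered list of atoms with a single coordinate set."""

    atoms: list[Atom] = field(default_factory=list)
    title: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.resid, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in structure")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @coords.setter
    def coords(self, value: np.ndarray) -> None:
        value = np.asarray(value, dtype=float)
        if value.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, xyz in zip(self.atoms, value):
            atom.coord = xyz.copy()

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def copy(self) -> "Structure":
        return Structure(
            atoms=[replace(a, coord=a.coord.copy()) for a in self.atoms],
            title=self.title,
        )

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, resid, resname) triples."""
        out: list[tuple[str, int, str]] = []
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.resid, a.resname)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def atom_index(self, chain: str, resid: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.chain == chain and a.resid == resid and a.name == name:
                return i
        raise KeyError(f"no atom {chain}:{resid}:{name}")

    def first_resid(self, chain: str) -> int:
        resids = [a.resid for a in self.atoms if a.chain == chain]
        if not resids:
            raise KeyError(f"no chain {chain}")
        return min(resids)


@dataclass
class Trajectory:
    """A topology plus one coordinate array per frame (Å)."""

    topology: Structure
    frames: list[np.ndarray] = field(default_factory=list)
    times: list[float] | None = None  # ns

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for i, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise PDBError(
                    f"inconsistent frame topology: frame {i} has shape "
                    f"{f.shape}, expected ({n}, 3)"
                )
        if self.times is not None:
            if len(self.times) != len(self.frames):
                raise ValueError("times length must match number of frames")
            if any(b <= a for a, b in zip(self.times, self.times[1:])):
                raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def frame_structure(self, index: int) -> Structure:
        s = self.topology.copy()
        s.coords = self.frames[index]
        return s

    @classmethod
    def from_structure(cls, structure: Structure) -> "Trajectory":
        return cls(topology=structure, frames=[structure.coords])


# ---------------------------------------------------------------------------
# Selection mini-language
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = {"and", "or", "not", "chain", "resid", "resname", "name",
             "element", "all", "(", ")"}


@dataclass(frozen=True)
class Selection:
    """A parsed selection expression.

    Grammar (case-insensitive keywords, values verbatim)::

        expr      := term ("or" term)*
        term      := factor ("and" factor)*
        factor    := "not" factor | "(" expr ")" | primitive
        primitive := "all"
                   | "chain"   VALUE+
                   | "resid"   (INT | INT-INT)+
                   | "resname" VALUE+
                   | "name"    VALUE+
                   | "element" VALUE+
    """

    expression: str

    def __post_init__(self) -> None:
        _parse(self.expression)  # parse eagerly: invalid expressions raise

    def mask(self, structure: Structure) -> np.ndarray:
        return _parse(self.expression)(structure)

    def indices(self, structure: Structure) -> list[int]:
        return [int(i) for i in np.nonzero(self.mask(structure))[0]]


def _parse(expression: str):
    tokens = _TOKEN_RE.findall(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = peek()
        pos += 1
        return tok

    def parse_expr():
        node = parse_term()
        while peek() is not None and peek().lower() == "or":
            take()
            rhs = parse_term()
            node = _or(node, rhs)
        return node

    def parse_term():
        node = parse_factor()
        while peek() is not None and peek().lower() == "and":
            take()
            rhs = parse_factor()
            node = _and(node, rhs)
        return node

    def parse_factor():
        tok = peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        if tok.lower() == "not":
            take()
            inner = parse_factor()
            return lambda s: ~inner(s)
        if tok == "(":
            take()
            inner = parse_expr()
            if take() != ")":
                raise SelectionError("unbalanced parentheses in selection")
            return inner
        return parse_primitive()

    def collect_values():
        vals = []
        while peek() is not None and peek().lower() not in _KEYWORDS:
            vals.append(take())
        if not vals:
            raise SelectionError("keyword requires at least one value")
        return vals

    def parse_primitive():
        tok = take().lower()
        if tok == "all":
            return lambda s: np.ones(len(s.atoms), dtype=bool)
        if tok == "chain":
            vals = set(collect_values())
            return lambda s: np.array([a.chain in vals for a in s.atoms])
        if tok == "resname":
            vals = {v.upper() for v in collect_values()}
            return lambda s: np.array(
                [a.resname.upper() in vals for a in s.atoms])
        if tok == "name":
            vals = {v.upper() for v in collect_values()}
            return lambda s: np.array([a.name.upper() in vals for a in s.atoms])
        if tok == "element":
            vals = {v.upper() for v in collect_values()}
            return lambda s: np.array(
                [a.element.upper() in vals for a in s.atoms])
        if tok == "resid":
            ranges = []
            for v in collect_values():
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", v)
                if not m:
                    raise SelectionError(f"bad resid token {v!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                if hi < lo:
                    raise SelectionError(f"empty resid range {v!r}")
                ranges.append((lo, hi))
            return lambda s: np.array(
                [any(lo <= a.resid <= hi for lo, hi in ranges)
                 for a in s.atoms])
        raise SelectionError(f"unknown selection keyword {tok!r}")

    def _and(a, b):
        return lambda s: a(s) & b(s)

    def _or(a, b):
        return lambda s: a(s) | b(s)

    root = parse_expr()
    if pos != len(tokens):
        raise SelectionError(
            f"trailing tokens in selection: {' '.join(tokens[pos:])}")
    return root


def select(traj: Trajectory | Structure, sel: Selection | str) -> list[int]:
    """Atom indices (topology order) matching a selection. Empty is legal."""
    if isinstance(sel, str):
        sel = Selection(sel)
    structure = traj.topology if isinstance(traj, Trajectory) else traj
    return sel.indices(structure)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path) -> Trajectory:
    """Read a (possibly multi-MODEL) PDB file into a Trajectory.

    Element is taken from columns 77-78 when present, otherwise inferred
    from the atom name.  Alternate locations other than blank/'A' are
    dropped; insertion codes are not supported and raise :class:`PDBError`.
    Every MODEL must contain the same atoms as the first, otherwise an
    ``inconsistent frame topology`` error is raised.
    """
    atoms: list[Atom] = []
    frames: list[np.ndarray] = []
    current: list[tuple] = []   # ((chain, resid, name), coord) per atom
    topology_done = False
    title = ""

    def finish_frame():
        nonlocal topology_done
        if not current:
            return
        if not topology_done:
            topology_done = True
        coords = np.array([c for _, c in current], dtype=float)
        if frames and coords.shape != frames[0].shape:
            raise PDBError("inconsistent frame topology")
        if topology_done and len(atoms) != len(current):
            raise PDBError("inconsistent frame topology")
        keys = [k for k, _ in current]
        expected = [(a.chain, a.resid, a.name) for a in atoms]
        if keys != expected:
            raise PDBError("inconsistent frame topology")
        frames.append(coords)
        current.clear()

    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "TITLE ":
                title = (title + " " + line[10:].strip()).strip()
            elif rec == "ENDMDL":
                finish_frame()
            elif rec in ("ATOM  ", "HETATM"):
                altloc = line[16]
                if altloc not in (" ", "A"):
                    continue
                icode = line[26]
                if icode != " ":
                    raise PDBError(
                        f"insertion codes unsupported (residue "
                        f"{line[22:26].strip()}{icode!r})")
                name = line[12:16].strip()
                resname = line[17:20].strip()
                chain = line[21]
                resid = int(line[22:26])
                coord = (float(line[30:38]), float(line[38:46]),
                         float(line[46:54]))
                element = line[76:78].strip() if len(line) >= 78 else ""
                if not topology_done and len(frames) == 0:
                    occ = _float_or(line[54:60], 1.0)
                    bf = _float_or(line[60:66], 0.0)
                    atoms.append(Atom(
                        serial=int(line[6:11]),
                        name=name, resname=resname, chain=chain, resid=resid,
                        coord=np.array(coord), element=element.capitalize(),
                        occupancy=occ, bfactor=bf, het=(rec == "HETATM"),
                    ))
                current.append(((chain, resid, name), np.array(coord)))
            elif rec in ("TER   ", "END   ", "END\n"):
                continue
    if current:
        finish_frame()
    if not atoms:
        raise PDBError(f"no ATOM/HETATM records in {path}")
    return Trajectory(topology=Structure(atoms=atoms, title=title),
                      frames=frames)


def _float_or(text: str, default: float) -> float:
    text = text.strip()
    if not text:
        return default
    try:
        return float(text)
    except ValueError:
        return default


def write_pdb(traj: Trajectory | Structure, path) -> None:
    """Write a Trajectory as fixed-width PDB; multi-frame uses MODEL blocks.

    Round-trip safe to 3 decimals (the PDB column width).
    """
    if isinstance(traj, Structure):
        traj = Trajectory.from_structure(traj)
    if traj.n_frames == 0 or traj.n_atoms == 0:
        raise ValueError("cannot write empty trajectory")
    multi = traj.n_frames > 1
    with open(path, "w") as fh:
        if traj.topology.title:
            fh.write(f"TITLE     {traj.topology.title}\n")
        for f, coords in enumerate(traj.frames):
            if multi:
                fh.write(f"MODEL     {f + 1}\n")
            for i, atom in enumerate(traj.topology.atoms):
                x, y, z = coords[i]
                rec = "HETATM" if atom.het else "ATOM  "
                name = atom.name
                # PDB atom-name alignment: 1-3 char names start in col 14
                # unless they begin with a 2-letter element symbol.
                if len(name) < 4 and name[:2].upper() not in _TWO_LETTER_ELEMENTS:
                    name_field = f" {name:<3s}"
                else:
                    name_field = f"{name:<4s}"
                fh.write(
                    f"{rec}{(i % 99999) + 1:5d} {name_field} "
                    f"{atom.resname:<3s} {atom.chain}{atom.resid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
                    f"{atom.bfactor:6.2f}          "
                    f"{atom.element.upper():>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
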