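"""Helix axes, TM rotation angles, superposition, distances and dihedrals.

The central quantity here is the per-helix rotation angle of a frame
relative to a reference frame.  It is computed in an axis-local way that
is invariant to whole-body rigid motion:

1. the frame is superposed onto the reference using the Cα atoms of *all*
   transmembrane segments (loops excluded, they are the mobile regions);
2. the reference helix axis and centroid are fitted (first principal
   component, oriented N→C);
3. every residue's Cα is projected onto the plane perpendicular to the
   axis through the centroid, in both frames;
4. the signed angle between the two projections (right-hand rule about
   the axis) is taken per residue and combined with a circular mean,
   wrapped to (−180, 180].

A cross-check estimator (`tm_rotation_angle_twist`) extracts the twist
component of the per-helix Kabsch rotation instead; the two agree within
a couple of degrees on well-formed helices.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation as _R

from .structure import Selection, Structure, Trajectory, select

logger = logging.getLogger(__name__)

__all__ = [
    "TMSegment",
    "TMSegmentSet",
    "cxcr3_segments",
    "helix_axis",
    "kabsch_superpose",
    "tm_rotation_angle",
    "tm_rotation_angle_twist",
    "rotation_series",
    "com_distance",
    "phi_psi",
    "RamachandranRegionMap",
    "default_region_map",
    "ramachandran_summary",
    "wrap_angle",
]


def wrap_angle(deg):
    """Wrap angle(s) in degrees to the interval (−180, 180]."""
    return -((-np.asarray(deg) + 180.0) % 360.0 - 180.0)


# ---------------------------------------------------------------------------
# TM segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TMSegment:
    name: str
    chain: str
    first: int
    last: int
    #: extra residues analysed together with this helix when
    #: ``include_extensions`` is requested (e.g. a DRY motif tail).
    extension: tuple[int, int] | None = None

    def __post_init__(self):
        if self.first > self.last:
            raise ValueError(f"{self.name}: first resid > last resid")

    def resid_range(self, include_extension: bool = False) -> tuple[int, int]:
        if include_extension and self.extension is not None:
            return (min(self.first, self.extension[0]),
                    max(self.last, self.extension[1]))
        return (self.first, self.last)

    def n_residues(self, include_extension: bool = False) -> int:
        lo, hi = self.resid_range(include_extension)
        return hi - lo + 1


@dataclass
class TMSegmentSet:
    """Ordered, non-overlapping named residue ranges (one per helix)."""

    segments: list[TMSegment] = field(default_factory=list)
    include_extensions: bool = False

    def __post_init__(self):
        by_chain: dict[str, list[TMSegment]] = {}
        for seg in self.segments:
            by_chain.setdefault(seg.chain, []).append(seg)
        for segs in by_chain.values():
            spans = sorted(s.resid_range(self.include_extensions)
                           for s in segs)
            for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
                if b_lo <= a_hi:
                    raise ValueError("overlapping TM segments")

    def __iter__(self):
        return iter(self.segments)

    def __len__(self):
        return len(self.segments)

    def names(self) -> list[str]:
        return [s.name for s in self.segments]

    def __getitem__(self, name: str) -> TMSegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def ca_selection(self, seg: TMSegment) -> Selection:
        lo, hi = seg.resid_range(self.include_extensions)
        return Selection(f"chain {seg.chain} and resid {lo}-{hi} and name CA")

    def all_ca_selection(self) -> Selection:
        parts = []
        for seg in self.segments:
            lo, hi = seg.resid_range(self.include_extensions)
            parts.append(f"(chain {seg.chain} and resid {lo}-{hi})")
        return Selection("(" + " or ".join(parts) + ") and name CA")


#: Default helix boundaries of the CXCR3-style receptor used throughout the
#: fixtures; TM3 carries the DRY tail 148-150 and TM5 the 234-235 tail as
#: optional extensions.
_CXCR3_RANGES = [
    ("TM1", 54, 80, None),
    ("TM2", 90, 110, None),
    ("TM3", 126, 147, (148, 150)),
    ("TM4", 170, 189, None),
    ("TM5", 213, 233, (234, 235)),
    ("TM6", 256, 277, None),
    ("TM7", 299, 321, None),
]


def cxcr3_segments(chain: str = "R",
                   include_extensions: bool = False) -> TMSegmentSet:
    return TMSegmentSet(
        segments=[TMSegment(n, chain, lo, hi, ext)
                  for n, lo, hi, ext in _CXCR3_RANGES],
        include_extensions=include_extensions,
    )


# ---------------------------------------------------------------------------
# Axes and superposition
# ---------------------------------------------------------------------------

def helix_axis(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fit a helix axis to Cα coordinates.

    Returns ``(axis, centroid)`` where *axis* is the first principal
    component of the centered coordinates, oriented so it points from the
    first towards the last residue.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 4:
        raise ValueError("helix axis needs at least 4 points")
    centroid = coords.mean(axis=0)
    # smooth over ~one helical turn before the PCA so the radial
    # oscillation of an incomplete final turn does not tilt the axis
    if coords.shape[0] >= 8:
        kernel = np.ones(4) / 4.0
        pca_pts = np.stack([np.convolve(coords[:, d], kernel, mode="valid")
                            for d in range(3)], axis=1)
    else:
        pca_pts = coords
    centered = pca_pts - pca_pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9:
        raise ValueError("degenerate coordinates: no principal axis")
    axis = vt[0]
    if np.dot(axis, coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis, centroid


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray,
                     fit_indices=None):
    """Optimal rigid superposition of *mobile* onto *target* (Kabsch).

    When *fit_indices* is given, the transform is computed on that subset
    but the RMSD is still reported over the fitted subset.  Returns
    ``(rotation (3,3), translation (3,), rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches *target*; the
    rotation is proper (det = +1, reflections sign-corrected).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError("point count mismatch")
    fit_m = mobile if fit_indices is None else mobile[fit_indices]
    fit_t = target if fit_indices is None else target[fit_indices]
    if fit_m.shape[0] < 3:
        raise ValueError("need at least 3 points to superpose")
    cm = fit_m.mean(axis=0)
    ct = fit_t.mean(axis=0)
    h = (fit_m - cm).T @ (fit_t - ct)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ct - rot @ cm
    moved = fit_m @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fit_t) ** 2, axis=1))))
    return rot, trans, rmsd


def _projected_angles(ref_seg: np.ndarray, frm_seg: np.ndarray,
                      axis: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Per-residue signed rotation angle about *axis* (degrees)."""
    u = ref_seg - centroid
    v = frm_seg - centroid
    u = u - np.outer(u @ axis, axis)
    v = v - np.outer(v @ axis, axis)
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    ok = (nu > 1e-6) & (nv > 1e-6)
    u, v = u[ok], v[ok]
    cross = np.cross(u, v) @ axis
    dot = np.sum(u * v, axis=1)
    return np.degrees(np.arctan2(cross, dot))


def _circular_mean_deg(angles_deg: np.ndarray) -> float:
    rad = np.radians(angles_deg)
    return float(wrap_angle(np.degrees(
        np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad))))))


def tm_rotation_angle(frame_coords: np.ndarray, ref_coords: np.ndarray,
                      seg_indices, fit_indices=None) -> float:
    """Rotation of one helix in *frame* relative to *reference*, degrees.

    *frame_coords*/*ref_coords* hold the Cα coordinates of the whole TM
    bundle (same atom order); *seg_indices* picks out the helix of
    interest, *fit_indices* the atoms used for the global superposition
    (default: all).  Result lies in (−180, 180].
    """
    frame_coords = np.asarray(frame_coords, dtype=float)
    ref_coords = np.asarray(ref_coords, dtype=float)
    seg_indices = np.asarray(seg_indices, dtype=int)
    if seg_indices.size < 4:
        raise ValueError("segment must resolve to at least 4 Cα atoms")
    rot, trans, _ = kabsch_superpose(frame_coords, ref_coords, fit_indices)
    fitted = frame_coords @ rot.T + trans
    ref_seg = ref_coords[seg_indices]
    frm_seg = fitted[seg_indices]
    axis, centroid = helix_axis(ref_seg)
    per_res = _projected_angles(ref_seg, frm_seg, axis, centroid)
    if per_res.size == 0:
        raise ValueError("all residues project onto the axis")
    return _circular_mean_deg(per_res)


def tm_rotation_angle_twist(frame_coords: np.ndarray, ref_coords: np.ndarray,
                            seg_indices, fit_indices=None) -> float:
    """Cross-check estimator: twist component of the per-helix rotation.

    After global superposition, the optimal rotation mapping the reference
    helix onto the frame helix is decomposed swing/twist about the
    reference axis; the twist angle is returned in degrees, (−180, 180].
    """
    frame_coords = np.asarray(frame_coords, dtype=float)
    ref_coords = np.asarray(ref_coords, dtype=float)
    seg_indices = np.asarray(seg_indices, dtype=int)
    if seg_indices.size < 4:
        raise ValueError("segment must resolve to at least 4 Cα atoms")
    rot, trans, _ = kabsch_superpose(frame_coords, ref_coords, fit_indices)
    fitted = frame_coords @ rot.T + trans
    ref_seg = ref_coords[seg_indices]
    frm_seg = fitted[seg_indices]
    axis, _ = helix_axis(ref_seg)
    seg_rot, _, _ = kabsch_superpose(ref_seg, frm_seg)
    quat = _R.from_matrix(seg_rot).as_quat()  # (x, y, z, w)
    proj = float(quat[:3] @ axis)
    twist = 2.0 * np.degrees(np.arctan2(proj, quat[3]))
    return float(wrap_angle(twist))


def rotation_series(traj: Trajectory, segments: TMSegmentSet,
                    ref_frame_index: int = 0, stride: int = 1,
                    mode: str = "reference") -> pd.DataFrame:
    """Per-frame, per-TM rotation angles vs a reference frame.

    ``mode="reference"`` (default) measures every frame against
    *ref_frame_index*; ``mode="delta"`` measures frame-to-frame changes.
    Returns a tidy frame with columns ``frame, time_ns, tm, angle_deg``.
    """
    if not 0 <= ref_frame_index < traj.n_frames:
        raise IndexError("reference frame index out of range")
    if mode not in ("reference", "delta"):
        raise ValueError("mode must be 'reference' or 'delta'")
    all_ca = select(traj, segments.all_ca_selection())
    if not all_ca:
        raise ValueError("segments select no Cα atoms")
    pos_in_bundle = {idx: i for i, idx in enumerate(all_ca)}
    seg_idx: dict[str, np.ndarray] = {}
    for seg in segments:
        idx = select(traj, segments.ca_selection(seg))
        if len(idx) < 4:
            raise ValueError(f"{seg.name} resolves to fewer than 4 Cα atoms")
        seg_idx[seg.name] = np.array([pos_in_bundle[i] for i in idx])

    frames = list(range(0, traj.n_frames, max(1, stride)))
    rows = []
    for k, f in enumerate(frames):
        if mode == "reference":
            ref = traj.frames[ref_frame_index][all_ca]
        else:
            prev = frames[k - 1] if k > 0 else f
            ref = traj.frames[prev][all_ca]
        cur = traj.frames[f][all_ca]
        t = traj.times[f] if traj.times is not None else float(f)
        n_bundle = len(all_ca)
        for seg in segments:
            # fit on the *other* helices so a genuine rotation of this one
            # is not partially absorbed by the rigid-motion removal
            fit = np.setdiff1d(np.arange(n_bundle), seg_idx[seg.name])
            ang = tm_rotation_angle(cur, ref, seg_idx[seg.name],
                                    fit_indices=fit)
            rows.append({"frame": f, "time_ns": t, "tm": seg.name,
                         "angle_deg": ang})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def com_distance(traj: Trajectory, sel_a: Selection | str,
                 sel_b: Selection | str,
                 mass_weighted: bool = True) -> np.ndarray:
    """Per-frame distance between the centers of two selections (Å)."""
    idx_a = select(traj, sel_a)
    idx_b = select(traj, sel_b)
    if not idx_a or not idx_b:
        raise ValueError("com_distance: empty selection")
    masses = traj.topology.masses
    wa = masses[idx_a] if mass_weighted else np.ones(len(idx_a))
    wb = masses[idx_b] if mass_weighted else np.ones(len(idx_b))
    out = np.empty(traj.n_frames)
    for f, coords in enumerate(traj.frames):
        ca = np.average(coords[idx_a], axis=0, weights=wa)
        cb = np.average(coords[idx_b], axis=0, weights=wb)
        out[f] = np.linalg.norm(ca - cb)
    return out


# ---------------------------------------------------------------------------
# Dihedrals and Ramachandran summaries
# ---------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 (IUPAC), degrees in (−180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def phi_psi(structure: Structure, chain: str | None = None
            ) -> list[tuple[int, float, float]]:
    """Backbone (φ, ψ) pairs per residue; termini and incomplete residues
    are skipped (with a warning for missing backbone atoms)."""
    chains = [chain] if chain is not None else structure.chains()
    results: list[tuple[int, float, float]] = []
    for ch in chains:
        backbone: dict[int, dict[str, np.ndarray]] = {}
        order: list[int] = []
        for a in structure.atoms:
            if a.chain != ch or a.name not in ("N", "CA", "C"):
                continue
            if a.resid not in backbone:
                backbone[a.resid] = {}
                order.append(a.resid)
            backbone[a.resid][a.name] = a.coord
        incomplete = [r for r in order if len(backbone[r]) < 3]
        if incomplete:
            warnings.warn(
                f"chain {ch}: skipping {len(incomplete)} residue(s) with "
                f"missing backbone atoms", stacklevel=2)
        complete = [r for r in order if len(backbone[r]) == 3]
        for prev, cur, nxt in zip(complete, complete[1:], complete[2:]):
            # require sequence neighbours, not just file neighbours
            if cur - prev != 1 or nxt - cur != 1:
                continue
            phi = dihedral(backbone[prev]["C"], backbone[cur]["N"],
                           backbone[cur]["CA"], backbone[cur]["C"])
            psi = dihedral(backbone[cur]["N"], backbone[cur]["CA"],
                           backbone[cur]["C"], backbone[nxt]["N"])
            results.append((cur, phi, psi))
    return results


@dataclass
class RamachandranRegionMap:
    """Polygonal φ/ψ regions with a class label; wrap-around aware.

    Classification precedence is favored > allowed; anything outside all
    polygons is an outlier.  Points are tested at ±360° shifts in both
    angles so polygons may be written in plain [−180, 180] coordinates.
    """

    regions: list[tuple[str, np.ndarray, str]]  # (name, (n,2) polygon, class)

    def classify(self, phi: float, psi: float) -> str:
        for wanted in ("favored", "allowed"):
            for _, poly, cls in self.regions:
                if cls != wanted:
                    continue
                for dphi in (0.0, 360.0, -360.0):
                    for dpsi in (0.0, 360.0, -360.0):
                        if _point_in_polygon(phi + dphi, psi + dpsi, poly):
                            return cls
        return "outlier"

    @classmethod
    def from_json(cls, path_or_dict) -> "RamachandranRegionMap":
        if isinstance(path_or_dict, dict):
            data = path_or_dict
        else:
            with open(path_or_dict) as fh:
                data = json.load(fh)
        regions = [(r["name"], np.asarray(r["polygon"], dtype=float),
                    r["class"]) for r in data["regions"]]
        return cls(regions=regions)


def _point_in_polygon(x: float, y: float, poly: np.ndarray) -> bool:
    """Even-odd rule; points on an edge count as inside."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xin = (x2 - x1) * (y - y1) / (y2 - y1) + x1
            if x <= xin:
                inside = not inside
    return inside


def default_region_map() -> RamachandranRegionMap:
    data = resources.files("gpcrkit.data").joinpath("rama_regions.json")
    return RamachandranRegionMap.from_json(json.loads(data.read_text()))


def ramachandran_summary(pairs, region_map: RamachandranRegionMap | None = None):
    """Percentage of residues in favored/allowed/outlier regions.

    *pairs* is a sequence of ``(resid, phi, psi)``.  Returns
    ``(fractions, table)`` where fractions is a dict of percentages
    summing to exactly 100 and table is a per-residue DataFrame.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no residues with complete (phi, psi)")
    if region_map is None:
        region_map = default_region_map()
    rows = [{"resid": r, "phi": phi, "psi": psi,
             "class": region_map.classify(phi, psi)}
            for r, phi, psi in pairs]
    table = pd.DataFrame(rows)
    n = len(table)
    fractions = {cls: 100.0 * (table["class"] == cls).sum() / n
                 for cls in ("favored", "allowed", "outlier")}
    return fractions, table
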