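"""End-to-end workflows behind the command-line interface.

Each workflow reads a flat configuration (YAML file and/or keyword
overrides), runs its stages with one log line per stage, and writes a
deterministic output bundle plus a manifest recording every effective
setting, so reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import gromos_cluster, pose_cluster, rmsd_matrix
from .geometry import (com_distance, cxcr3_segments, phi_psi,
                       ramachandran_summary, rotation_series, TMSegment,
                       TMSegmentSet)
from .interactions import (InteractionCriteria, arginine_cage_state,
                           contact_timetable, presence_table,
                           records_to_dataframe)
from .pharmacophore import build_consensus, compare_models, extract_features
from .poses import read_sdf, write_sdf
from .structure import read_pdb, write_pdb

logger = logging.getLogger("gpcrkit.pipeline")

_FLOAT_FMT = "%.6f"


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class RunConfig:
    workflow: str = "activation"            # activation | pharmacophore | simulate
    traj: str | None = None
    receptor_chain: str = "R"
    ligand_chain: str | None = None
    poses: str | None = None
    receptors: list[str] = field(default_factory=list)
    out: str = "out"
    seed: int = 0
    stride: int = 1
    segments: list[dict] | None = None      # [{name, chain, first, last}, ...]
    include_extensions: bool = False
    cluster_cutoff_nm: float = 0.6
    cluster_selection: str = "name CA"
    pose_rmsd_cutoff: float = 2.0
    annotation_radius: float = 5.0
    min_support: int | None = None
    pki_min: float | None = None
    pki_max: float | None = None
    arg_cage_resids: tuple[int, int] = (148, 149)
    hbond_da_max: float = 3.5
    hydrophobic_cc_max: float = 3.9
    saltbridge_max: float = 4.0
    his_positive: bool = False

    @classmethod
    def load(cls, path=None, **overrides) -> "RunConfig":
        data = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.arg_cage_resids, list):
            cfg.arg_cage_resids = tuple(cfg.arg_cage_resids)
        return cfg

    def criteria(self) -> InteractionCriteria:
        return InteractionCriteria(
            hbond_da_max=self.hbond_da_max,
            hydrophobic_cc_max=self.hydrophobic_cc_max,
            saltbridge_max=self.saltbridge_max,
            his_positive=self.his_positive,
        )

    def segment_set(self) -> TMSegmentSet:
        if self.segments is None:
            return cxcr3_segments(self.receptor_chain,
                                  self.include_extensions)
        segs = [TMSegment(name=s["name"], chain=s.get("chain",
                                                      self.receptor_chain),
                          first=int(s["first"]), last=int(s["last"]),
                          extension=tuple(s["extension"])
                          if s.get("extension") else None)
                for s in self.segments]
        return TMSegmentSet(segments=segs,
                            include_extensions=self.include_extensions)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _manifest(cfg: RunConfig, outdir: Path, extra: dict | None = None) -> None:
    payload = asdict(cfg)
    payload["arg_cage_resids"] = list(cfg.arg_cage_resids)
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()
    manifest = {
        "config": payload,
        "config_sha256": digest,
        "seed": cfg.seed,
        "versions": {"gpcrkit": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    if extra:
        manifest.update(extra)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _run_stages(outdir: Path, stages) -> None:
    written: list[Path] = []
    for name, fn in stages:
        try:
            produced = fn()
            if produced:
                written.extend(produced)
            logger.info("stage %s done", name)
        except Exception as exc:
            for p in written:
                if p.exists():
                    p.unlink()
            raise StageError(f"stage '{name}' failed: {exc}") from exc


def run_activation(cfg: RunConfig) -> Path:
    """Rotation series, contact tables, distances, clustering and
    backbone-dihedral summary for one trajectory."""
    if not cfg.traj:
        raise StageError("stage 'load' failed: no trajectory given")
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)
    traj = read_pdb(cfg.traj)
    chains = traj.topology.chains()
    if cfg.receptor_chain not in chains:
        raise StageError(
            f"stage 'load' failed: receptor chain {cfg.receptor_chain!r} "
            f"not in trajectory (chains: {chains})")
    if cfg.ligand_chain is not None and cfg.ligand_chain not in chains:
        raise StageError(
            f"stage 'load' failed: ligand chain selection "
            f"{cfg.ligand_chain!r} not in trajectory (chains: {chains})")
    logger.info("loaded %d frames, %d atoms", traj.n_frames, traj.n_atoms)
    segments = cfg.segment_set()
    criteria = cfg.criteria()
    rsel = f"chain {cfg.receptor_chain}"
    lsel = f"chain {cfg.ligand_chain}" if cfg.ligand_chain else None

    def stage_rotation():
        series = rotation_series(traj, segments, stride=cfg.stride)
        _write_csv(series, outdir / "rotation_series.csv")
        return [outdir / "rotation_series.csv"]

    def stage_cage():
        d, r = cfg.arg_cage_resids
        table = arginine_cage_state(
            traj, (cfg.receptor_chain, d), (cfg.receptor_chain, r),
            criteria, stride=cfg.stride)
        out = table.copy()
        out["present"] = np.where(out["present"], "X", "")
        _write_csv(out, outdir / "arginine_cage.csv")
        return [outdir / "arginine_cage.csv"]

    def stage_contacts():
        if lsel is None:
            raise ValueError("contact analysis needs --ligand-chain")
        records, presence, counts = contact_timetable(
            traj, rsel, lsel, criteria, stride=cfg.stride)
        _write_csv(records_to_dataframe(records), outdir / "contacts.csv")
        _write_csv(presence_table(presence),
                   outdir / "contact_timetable.csv")
        _write_csv(counts, outdir / "contact_counts.csv")
        return [outdir / "contacts.csv", outdir / "contact_timetable.csv",
                outdir / "contact_counts.csv"]

    def stage_distance():
        if lsel is None:
            raise ValueError("distance analysis needs --ligand-chain")
        d = com_distance(traj, rsel, lsel)
        frames = list(range(traj.n_frames))
        times = traj.times or [float(f) for f in frames]
        _write_csv(pd.DataFrame({"frame": frames, "time_ns": times,
                                 "distance_A": d}),
                   outdir / "com_distance.csv")
        return [outdir / "com_distance.csv"]

    def stage_cluster():
        if traj.n_frames < 2:
            logger.info("single frame: skipping clustering")
            return []
        sel = f"({cfg.cluster_selection}) and chain {cfg.receptor_chain}"
        matrix = rmsd_matrix(traj, sel, superpose=True, units="nm")
        result = gromos_cluster(matrix, cfg.cluster_cutoff_nm)
        result.to_json(outdir / "clusters.json")
        logger.info("%d clusters at %.2f nm", result.n_clusters,
                    cfg.cluster_cutoff_nm)
        return [outdir / "clusters.json"]

    def stage_rama():
        pairs = phi_psi(traj.frame_structure(0), cfg.receptor_chain)
        if not pairs:
            logger.warning("no complete backbone: ramachandran skipped")
            _write_csv(pd.DataFrame(
                columns=["resid", "phi", "psi", "class"]),
                outdir / "ramachandran.csv")
            return [outdir / "ramachandran.csv"]
        fractions, table = ramachandran_summary(pairs)
        _write_csv(table, outdir / "ramachandran.csv")
        with open(outdir / "ramachandran_summary.json", "w") as fh:
            json.dump(fractions, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return [outdir / "ramachandran.csv",
                outdir / "ramachandran_summary.json"]

    stages = [("rotation", stage_rotation), ("arginine_cage", stage_cage)]
    if lsel is not None:
        stages += [("contacts", stage_contacts),
                   ("com_distance", stage_distance)]
    stages += [("clustering", stage_cluster), ("ramachandran", stage_rama)]
    _run_stages(outdir, stages)
    _manifest(cfg, outdir)
    return outdir


def run_pharmacophore(cfg: RunConfig) -> Path:
    """Pose clustering, feature extraction and consensus models, one per
    receptor conformation; plus a comparison table when several are given."""
    if not cfg.poses:
        raise StageError("stage 'load' failed: no pose file given")
    if not cfg.receptors:
        raise StageError("stage 'load' failed: no receptor structure given")
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)
    pose_set = read_sdf(cfg.poses)
    if cfg.pki_min is not None or cfg.pki_max is not None:
        lo = cfg.pki_min if cfg.pki_min is not None else -np.inf
        hi = cfg.pki_max if cfg.pki_max is not None else np.inf
        pose_set = pose_set.filter_pki(lo, hi)
    if len(pose_set) == 0:
        raise StageError("stage 'filter' failed: empty library after "
                         "pKi filtering")
    logger.info("loaded %d poses / %d ligands", len(pose_set),
                len(pose_set.ligand_ids()))

    models = {}

    def make_conformation_stage(rec_path: str):
        name = Path(rec_path).stem

        def stage():
            receptor = read_pdb(rec_path).frame_structure(0)
            results, representatives = pose_cluster(
                pose_set, cfg.pose_rmsd_cutoff)
            with open(outdir / f"{name}_pose_clusters.json", "w") as fh:
                json.dump({lig: res.to_dict()
                           for lig, res in results.items()},
                          fh, indent=2, default=str)
                fh.write("\n")
            reps = pose_set.subset(representatives)
            feat_rows = []
            for pose in reps:
                for f in extract_features(pose):
                    feat_rows.append({
                        "ligand_id": f.ligand_id, "pose_id": f.pose_id,
                        "type": f.type,
                        "x": f.position[0], "y": f.position[1],
                        "z": f.position[2], "radius": f.radius,
                    })
            _write_csv(pd.DataFrame(feat_rows),
                       outdir / f"{name}_features.csv")
            model = build_consensus(
                pose_set, receptor, min_support=cfg.min_support,
                annotation_radius=cfg.annotation_radius,
                representatives=representatives)
            model.to_json(outdir / f"{name}_consensus.json")
            _write_csv(model.residues_table(),
                       outdir / f"{name}_consensus_residues.csv")
            models[name] = model
            logger.info("%s: %d consensus elements", name,
                        len(model.elements))
            return [outdir / f"{name}_pose_clusters.json",
                    outdir / f"{name}_features.csv",
                    outdir / f"{name}_consensus.json",
                    outdir / f"{name}_consensus_residues.csv"]
        return stage

    stages = [(f"consensus:{Path(p).stem}", make_conformation_stage(p))
              for p in cfg.receptors]

    def stage_compare():
        names = list(models)
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rep = compare_models(models[names[i]], models[names[j]])
                rep.insert(0, "model_a", names[i])
                rep.insert(1, "model_b", names[j])
                rows.append(rep)
        _write_csv(pd.concat(rows, ignore_index=True),
                   outdir / "model_comparison.csv")
        return [outdir / "model_comparison.csv"]

    if len(cfg.receptors) >= 2:
        stages.append(("comparison", stage_compare))
    _run_stages(outdir, stages)
    _manifest(cfg, outdir)
    return outdir


# ---------------------------------------------------------------------------
# Fixture presets
# ---------------------------------------------------------------------------

def run_simulate(preset: str, seed: int, out: str) -> Path:
    """Write one of the shipped synthetic fixtures and its ground truth."""
    from .synth import (ContactPlant, PoseClusterSpec, PoseLibrarySpec,
                        RotationSchedule, decorate_residue,
                        make_complex_trajectory, make_pose_library,
                        make_rotated_trajectory, make_tm_bundle,
                        seven_tm_bundle, seven_tm_specs)

    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    if preset == "rotation":
        bundle, segments = seven_tm_bundle()
        schedule = RotationSchedule(n_frames=6, angles={
            2: {"TM6": 15.0}, 3: {"TM6": 15.0, "TM5": -10.0},
            4: {"TM6": 45.0, "TM1": 5.0}, 5: {"TM6": -150.0},
        })
        traj, truth = make_rotated_trajectory(
            bundle, segments, schedule, noise_sd=0.1,
            global_motion="random", seed=seed)
        write_pdb(traj, outdir / "rotation_fixture.pdb")
        _write_csv(truth, outdir / "rotation_truth.csv")
    elif preset == "approach":
        bundle, segments = seven_tm_bundle()
        bundle = decorate_residue(bundle, "R", 148, "ASP")
        ligand, _ = make_tm_bundle(
            [s for s in seven_tm_specs(chain="Q")[:2]])
        ligand = decorate_residue(ligand, "Q", 60, "ARG")
        plants = [ContactPlant(("R", 148, "OD1"), ("Q", 60, "NH1"),
                               "saltbridge", frozenset({3, 4}))]
        traj, truth = make_complex_trajectory(
            bundle, ligand, [60.0, 55.0, 50.0, 45.0, 40.0], plants,
            seed=seed)
        write_pdb(traj, outdir / "approach_fixture.pdb")
        _write_csv(truth, outdir / "approach_truth.csv")
    elif preset == "poses":
        spec = PoseLibrarySpec(
            clusters=[
                PoseClusterSpec("Arm", np.array([0.0, 0.0, 0.0]),
                                0.3, 10),
                PoseClusterSpec("NIn", np.array([12.0, 0.0, 0.0]),
                                0.3, 10),
            ],
            n_outlier_poses=1, seed=seed)
        pose_set, truth = make_pose_library(spec)
        write_sdf(pose_set, outdir / "pose_library.sdf")
        with open(outdir / "pose_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return outdir
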