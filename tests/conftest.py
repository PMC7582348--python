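import numpy as np
import pytest

from gpcrkit.synth import (ContactPlant, HelixSpec, PoseClusterSpec,
                           PoseLibrarySpec, RotationSchedule,
                           decorate_residue, make_complex_trajectory,
                           make_pose_library, make_rotated_trajectory,
                           make_tm_bundle, seven_tm_bundle)


@pytest.fixture(scope="session")
def bundle_and_segments():
    return seven_tm_bundle()


@pytest.fixture(scope="session")
def bundle(bundle_and_segments):
    return bundle_and_segments[0]


@pytest.fixture(scope="session")
def segments(bundle_and_segments):
    return bundle_and_segments[1]


@pytest.fixture(scope="session")
def rotation_fixture(bundle_and_segments):
    """Noiseless planted rotations: TM6 +15° (frame 1), TM6 −150° (frame 2)."""
    bundle, segments = bundle_and_segments
    schedule = RotationSchedule(
        n_frames=3, angles={1: {"TM6": 15.0}, 2: {"TM6": -150.0}})
    traj, truth = make_rotated_trajectory(bundle, segments, schedule,
                                          noise_sd=0.0, seed=0)
    return traj, truth, schedule


def _two_helix_chain(chain, x0):
    specs = [
        HelixSpec(n_res=20, chain=chain, start_resid=1,
                  axis_origin=np.array([x0, 0.0, 0.0])),
        HelixSpec(n_res=20, chain=chain, start_resid=30,
                  axis_origin=np.array([x0 + 8.0, 0.0, 0.0])),
    ]
    return make_tm_bundle(specs)[0]


@pytest.fixture(scope="session")
def complex_fixture(bundle_and_segments):
    """Receptor-ligand approach with one plant of each interaction kind."""
    bundle, _ = bundle_and_segments
    receptor = decorate_residue(bundle, "R", 148, "ASP")
    receptor = decorate_residue(receptor, "R", 216, "ARG")
    ligand = _two_helix_chain("Q", 60.0)
    ligand = decorate_residue(ligand, "Q", 5, "ARG")
    ligand = decorate_residue(ligand, "Q", 35, "SER")
    ligand = decorate_residue(ligand, "Q", 10, "LEU")
    plants = [
        ContactPlant(("R", 148, "OD1"), ("Q", 5, "NH1"), "saltbridge",
                     frozenset({0, 1})),
        ContactPlant(("R", 216, "NH1"), ("Q", 35, "OG"), "hbond",
                     frozenset({1, 2})),
        ContactPlant(("R", 148, "CB"), ("Q", 10, "CD1"), "hydrophobic",
                     frozenset({2})),
    ]
    traj, truth = make_complex_trajectory(
        receptor, ligand, [40.0, 35.0, 30.0], plants, seed=0)
    return traj, truth


@pytest.fixture(scope="session")
def pose_library():
    spec = PoseLibrarySpec(
        clusters=[
            PoseClusterSpec("Arm", np.array([0.0, 0.0, 0.0]), 0.3, 10),
            PoseClusterSpec("NIn", np.array([12.0, 0.0, 0.0]), 0.3, 10),
        ],
        n_outlier_poses=1, seed=7)
    return make_pose_library(spec)
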