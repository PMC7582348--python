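import numpy as np
import pytest

from gpcrkit.geometry import (com_distance, cxcr3_segments, default_region_map,
                              dihedral, helix_axis, kabsch_superpose, phi_psi,
                              ramachandran_summary, rotation_series,
                              tm_rotation_angle, tm_rotation_angle_twist,
                              wrap_angle, TMSegment, TMSegmentSet)
from gpcrkit.structure import Atom, Structure, Trajectory
from gpcrkit.synth import (HelixSpec, RotationSchedule, make_ideal_helix,
                           make_rotated_trajectory, random_rigid_transform)


def brute_force_min_rmsd(mobile, target, coarse=5.0, fine=1.0):
    """Grid-search superposition oracle: full sweep of Euler angles at
    *coarse* degrees, then *fine*-degree refinement around the best cell,
    with centroids matched."""
    mobile = mobile - mobile.mean(axis=0)
    target = target - target.mean(axis=0)

    def rmsd_for(angles):
        a, b, c = np.radians(angles)
        rz1 = np.array([[np.cos(a), -np.sin(a), 0],
                        [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0],
                       [-np.sin(b), 0, np.cos(b)]])
        rz2 = np.array([[np.cos(c), -np.sin(c), 0],
                        [np.sin(c), np.cos(c), 0], [0, 0, 1]])
        moved = mobile @ (rz1 @ ry @ rz2).T
        return np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1)))

    best, best_angles = np.inf, None
    grid = np.arange(0.0, 360.0, coarse)
    grid_b = np.arange(0.0, 180.0 + coarse, coarse)
    for a in grid:
        for b in grid_b:
            for c in grid:
                r = rmsd_for((a, b, c))
                if r < best:
                    best, best_angles = r, (a, b, c)
    a0, b0, c0 = best_angles
    rng = np.arange(-coarse, coarse + fine, fine)
    for da in rng:
        for db in rng:
            for dc in rng:
                r = rmsd_for((a0 + da, b0 + db, c0 + dc))
                best = min(best, r)
    return best


class TestHelixAxis:
    def test_z_helix(self):
        h = make_ideal_helix(HelixSpec(n_res=20))
        axis, _ = helix_axis(h.coords)
        assert np.degrees(np.arccos(np.clip(axis @ [0, 0, 1], -1, 1))) < 1.0

    def test_reversed_order_flips(self):
        h = make_ideal_helix(HelixSpec(n_res=20))
        axis, _ = helix_axis(h.coords[::-1])
        assert np.degrees(np.arccos(np.clip(axis @ [0, 0, -1], -1, 1))) < 1.0

    def test_three_points_rejected(self):
        with pytest.raises(ValueError):
            helix_axis(np.eye(3))


class TestKabsch:
    def test_identical_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        _, _, rmsd = kabsch_superpose(pts, pts)
        assert rmsd < 1e-12

    def test_rigid_transform_zero(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        rot, trans = random_rigid_transform(rng)
        _, _, rmsd = kabsch_superpose(pts, pts @ rot.T + trans)
        assert rmsd < 1e-9

    def test_90_degrees_about_z(self):
        pts = np.array([[1.0, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]])
        rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        _, _, rmsd = kabsch_superpose(pts, pts @ rz.T + np.array([3, 4, 5.0]))
        assert rmsd < 1e-9

    @pytest.mark.parametrize("seed", [2, 3])
    def test_against_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mobile = rng.normal(size=(4, 3))
        target = rng.normal(size=(4, 3))
        _, _, rmsd = kabsch_superpose(mobile, target)
        oracle = brute_force_min_rmsd(mobile, target)
        assert rmsd <= oracle + 1e-9
        assert abs(rmsd - oracle) < 1e-3

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3))
        _, _, r_ab = kabsch_superpose(a, b)
        _, _, r_ba = kabsch_superpose(b, a)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        assert r_ab >= 0

    def test_count_mismatch(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_reflection_not_allowed(self):
        # mirrored points must not be matched by an improper rotation
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        rot, _, rmsd = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1


class TestRotationAngle:
    def test_planted_rotation_exact(self, bundle, segments):
        schedule = RotationSchedule(n_frames=2, angles={1: {"TM3": 15.0}})
        traj, _ = make_rotated_trajectory(bundle, segments, schedule)
        series = rotation_series(traj, segments)
        got = series[(series.frame == 1) & (series.tm == "TM3")
                     ].angle_deg.iloc[0]
        assert got == pytest.approx(15.0, abs=0.01)

    def test_whole_body_motion_reads_zero(self, bundle, segments):
        rng = np.random.default_rng(6)
        rot, trans = random_rigid_transform(rng)
        schedule = RotationSchedule(n_frames=2)
        traj, _ = make_rotated_trajectory(
            bundle, segments, schedule,
            global_motion=[None, (rot, trans)])
        series = rotation_series(traj, segments)
        assert series[series.frame == 1].angle_deg.abs().max() < 0.01

    def test_wraparound(self, bundle, segments):
        # a 190° physical rotation reads as -170°
        schedule = RotationSchedule(n_frames=2, angles={1: {"TM6": 190.0}})
        traj, _ = make_rotated_trajectory(bundle, segments, schedule)
        series = rotation_series(traj, segments)
        got = series[(series.frame == 1) & (series.tm == "TM6")
                     ].angle_deg.iloc[0]
        assert got == pytest.approx(-170.0, abs=0.01)

    def test_range_invariant(self, bundle, segments):
        rng = np.random.default_rng(7)
        angles = {1: {"TM1": 170.0, "TM5": -179.0},
                  2: {"TM1": -45.0, "TM6": 400.0}}
        traj, _ = make_rotated_trajectory(
            bundle, segments, RotationSchedule(n_frames=3, angles=angles),
            noise_sd=0.1, global_motion="random", seed=8)
        series = rotation_series(traj, segments)
        assert (series.angle_deg > -180).all()
        assert (series.angle_deg <= 180).all()

    def test_rigid_invariance_property(self, bundle, segments):
        """Estimates change < 0.01° under any whole-body rigid motion."""
        schedule = RotationSchedule(n_frames=2, angles={1: {"TM6": 33.0}})
        traj, _ = make_rotated_trajectory(bundle, segments, schedule)
        base = rotation_series(traj, segments)
        rng = np.random.default_rng(9)
        for _ in range(3):
            rot, trans = random_rigid_transform(rng)
            moved = Trajectory(
                topology=traj.topology,
                frames=[traj.frames[0], traj.frames[1] @ rot.T + trans])
            series = rotation_series(moved, segments)
            assert np.abs(series.angle_deg.values
                          - base.angle_deg.values).max() < 0.01

    def test_twist_crosscheck_agrees(self, bundle, segments):
        schedule = RotationSchedule(
            n_frames=2, angles={1: {"TM2": 25.0, "TM7": -60.0}})
        traj, _ = make_rotated_trajectory(bundle, segments, schedule,
                                          noise_sd=0.1, seed=10)
        from gpcrkit.structure import select
        all_ca = select(traj, segments.all_ca_selection())
        pos = {idx: i for i, idx in enumerate(all_ca)}
        for seg in segments:
            idx = select(traj, segments.ca_selection(seg))
            seg_idx = np.array([pos[i] for i in idx])
            fit = np.setdiff1d(np.arange(len(all_ca)), seg_idx)
            a = tm_rotation_angle(traj.frames[1][all_ca],
                                  traj.frames[0][all_ca], seg_idx, fit)
            b = tm_rotation_angle_twist(traj.frames[1][all_ca],
                                        traj.frames[0][all_ca], seg_idx, fit)
            assert abs(wrap_angle(a - b)) < 2.0

    def test_short_segment_rejected(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            tm_rotation_angle(pts, pts, [0, 1, 2])

    def test_delta_mode_and_stride(self, bundle, segments):
        schedule = RotationSchedule(
            n_frames=10, angles={f: {"TM1": 3.0 * f} for f in range(1, 10)})
        traj, _ = make_rotated_trajectory(bundle, segments, schedule)
        assert len(rotation_series(traj, segments, stride=2)) == 5 * 7
        delta = rotation_series(traj, segments, mode="delta")
        tm1 = delta[delta.tm == "TM1"].angle_deg.values
        assert np.allclose(tm1[1:], 3.0, atol=0.05)


class TestSegments:
    def test_defaults_match_reference_table(self):
        segs = cxcr3_segments()
        assert segs["TM3"].extension == (148, 150)
        assert segs["TM5"].extension == (234, 235)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TMSegmentSet(segments=[TMSegment("A", "R", 1, 10),
                                   TMSegment("B", "R", 5, 20)])

    def test_reversed_range_rejected(self):
        with pytest.raises(ValueError):
            TMSegment("A", "R", 10, 1)


class TestComDistance:
    @staticmethod
    def _two_atoms(el_a="C", el_b="C"):
        atoms = [
            Atom(serial=1, name="C1", resname="LIG", chain="A", resid=1,
                 coord=np.zeros(3), element=el_a),
            Atom(serial=2, name="C2", resname="LIG", chain="B", resid=1,
                 coord=np.array([3.0, 4.0, 0.0]), element=el_b),
        ]
        return Trajectory.from_structure(Structure(atoms=atoms))

    def test_3_4_5(self):
        traj = self._two_atoms()
        assert com_distance(traj, "chain A", "chain B")[0] == \
            pytest.approx(5.0)

    def test_schedule_match(self, complex_fixture):
        traj, _ = complex_fixture
        d = com_distance(traj, "chain R", "chain Q")
        assert np.allclose(d, [40.0, 35.0, 30.0], atol=0.01)

    def test_mass_weighting_identical_for_homonuclear(self):
        traj = self._two_atoms()
        a = com_distance(traj, "chain A", "chain B", mass_weighted=True)
        b = com_distance(traj, "chain A", "chain B", mass_weighted=False)
        assert np.allclose(a, b)

    def test_empty_selection(self):
        traj = self._two_atoms()
        with pytest.raises(ValueError, match="empty"):
            com_distance(traj, "chain A", "chain Z")


class TestPhiPsi:
    def test_two_residue_chain(self):
        h = make_ideal_helix(HelixSpec(n_res=4, mode="backbone"))
        keep = [a for a in h.atoms if a.resid <= 2]
        pairs = phi_psi(Structure(atoms=keep))
        assert len(pairs) <= 1

    def test_calpha_only_warns_empty(self, bundle):
        with pytest.warns(UserWarning):
            pairs = phi_psi(bundle, "R")
        assert pairs == []

    def test_dihedral_convention(self):
        # trans (180°) butane-like arrangement
        p = [np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 0.0]),
             np.array([1.0, 0.0, 0.0]), np.array([1.0, -1.0, 0.0])]
        assert abs(dihedral(*p)) == pytest.approx(180.0)


class TestRamachandran:
    def test_ideal_helix_all_favored(self):
        h = make_ideal_helix(HelixSpec(n_res=20, mode="backbone"))
        fractions, _ = ramachandran_summary(phi_psi(h))
        assert fractions["favored"] == pytest.approx(100.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no residues"):
            ramachandran_summary([])

    def test_origin_is_outlier(self):
        fractions, table = ramachandran_summary([(1, 0.0, 0.0)])
        assert fractions["outlier"] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(11)
        pairs = [(i, rng.uniform(-180, 180), rng.uniform(-180, 180))
                 for i in range(50)]
        fractions, _ = ramachandran_summary(pairs)
        assert sum(fractions.values()) == pytest.approx(100.0, abs=1e-9)

    def test_wraparound_beta(self):
        # psi = -175 belongs to the wrapped part of the beta region
        fractions, _ = ramachandran_summary([(1, -120.0, -175.0)])
        assert fractions["favored"] == pytest.approx(100.0)

    def test_map_classification_total(self):
        m = default_region_map()
        assert m.classify(-57, -47) == "favored"
        assert m.classify(0, 0) == "outlier"
        assert m.classify(60, 40) == "allowed"


class TestWrapAngle:
    @pytest.mark.parametrize("x,expected", [
        (180.0, 180.0), (-180.0, 180.0), (190.0, -170.0),
        (-170.0 - 360.0, -170.0), (0.0, 0.0), (540.0, 180.0)])
    def test_values(self, x, expected):
        assert wrap_angle(x) == pytest.approx(expected)
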