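import itertools

import numpy as np
import pytest

from gpcrkit.pharmacophore import (ConsensusModel, FeatureRules,
                                   annotate_residues, build_consensus,
                                   choose_k, compare_models,
                                   extract_features,
                                   feature_distance_matrix, pam_kmedoids,
                                   silhouette_mean)
from gpcrkit.poses import LigandPose, PoseSet
from gpcrkit.synth import (PoseClusterSpec, PoseLibrarySpec, TEMPLATES,
                           make_pose_library, seven_tm_bundle)


def pam_brute_force(dist, k):
    """Exhaustive optimum over all medoid subsets."""
    n = dist.shape[0]
    best = (np.inf, None)
    for subset in itertools.combinations(range(n), k):
        cost = float(dist[:, subset].min(axis=1).sum())
        if cost < best[0] - 1e-12:
            best = (cost, subset)
    return best


def _mol(elements, coords, bonds, charges=None, aromatic=None):
    return LigandPose(
        ligand_id="m", pose_id="p0", elements=list(elements),
        coords=np.asarray(coords, dtype=float), bonds=list(bonds),
        charges=list(charges) if charges else [],
        aromatic=list(aromatic) if aromatic else [])


def benzene():
    coords = [(1.39 * np.cos(a), 1.39 * np.sin(a), 0.0)
              for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
    bonds = [(i, (i + 1) % 6, 12) for i in range(6)]
    return _mol(["C"] * 6, coords, bonds, aromatic=[True] * 6)


def ethanol():
    return _mol(["C", "C", "O"],
                [(-2.4, 0.4, 0.0), (-1.2, -0.4, 0.0), (0.0, 0.4, 0.0)],
                [(0, 1, 1), (1, 2, 1)])


def acetate():
    return _mol(["C", "C", "O", "O"],
                [(-2.13, 0.0, 0.0), (-0.63, 0.0, 0.0),
                 (0.0, 1.06, 0.0), (0.0, -1.06, 0.0)],
                [(0, 1, 1), (1, 2, 2), (1, 3, 1)],
                charges=[0, 0, 0, -1])


class TestExtractFeatures:
    def test_benzene_single_arm(self):
        feats = extract_features(benzene())
        assert [f.type for f in feats] == ["Arm"]
        assert np.linalg.norm(feats[0].position) < 1e-9

    def test_ethanol_hac_hdn(self):
        feats = extract_features(ethanol())
        types = sorted(f.type for f in feats)
        assert types == ["HAc", "HDn"]
        for f in feats:
            assert np.allclose(f.position, [0.0, 0.4, 0.0])

    def test_acetate_nin_no_hdn(self):
        feats = extract_features(acetate())
        types = [f.type for f in feats]
        assert types.count("NIn") == 1
        assert "HDn" not in types
        nin = next(f for f in feats if f.type == "NIn")
        assert np.allclose(nin.position, [0.0, 0.0, 0.0], atol=1e-9)

    def test_butane_hydrophobic(self):
        m = _mol(["C"] * 4,
                 [(-1.95, -0.4, 0), (-0.65, 0.4, 0), (0.65, -0.4, 0),
                  (1.95, 0.4, 0)],
                 [(0, 1, 1), (1, 2, 1), (2, 3, 1)])
        feats = extract_features(m)
        assert [f.type for f in feats] == ["Hph"]

    def test_methylammonium_pin_only(self):
        m = _mol(["C", "N"], [(-1.49, 0, 0), (0, 0, 0)], [(0, 1, 1)],
                 charges=[0, 1])
        assert [f.type for f in extract_features(m)] == ["PIn"]

    def test_neutral_amine_is_protonatable(self):
        m = _mol(["C", "N"], [(-1.49, 0, 0), (0, 0, 0)], [(0, 1, 1)])
        types = sorted(f.type for f in extract_features(m))
        assert "PIn" in types

    def test_amide_n_not_acceptor(self):
        # formamide-like fragment: N-C(=O)
        m = _mol(["N", "C", "O"],
                 [(-1.34, 0, 0), (0, 0, 0), (0.6, 1.06, 0)],
                 [(0, 1, 1), (1, 2, 2)])
        feats = extract_features(m)
        n_feats = [f.type for f in feats if f.atom_indices == (0,)]
        assert "HAc" not in n_feats
        assert "HDn" in n_feats

    def test_dangling_bond_rejected(self):
        with pytest.raises(ValueError, match="dangling"):
            _mol(["C"], [(0, 0, 0)], [(0, 3, 1)])

    def test_invariance_to_rigid_motion(self):
        from gpcrkit.synth import random_rigid_transform
        rng = np.random.default_rng(0)
        rot, trans = random_rigid_transform(rng)
        pose = acetate()
        moved = pose.transformed(rot, trans)
        fa = extract_features(pose)
        fb = extract_features(moved)
        assert [f.type for f in fa] == [f.type for f in fb]
        for a, b in zip(fa, fb):
            assert np.allclose(rot @ a.position + trans, b.position,
                               atol=1e-9)

    def test_invariance_to_atom_reordering(self):
        pose = acetate()
        order = [3, 1, 0, 2]
        inverse = {old: new for new, old in enumerate(order)}
        reordered = LigandPose(
            ligand_id="m", pose_id="p0",
            elements=[pose.elements[i] for i in order],
            coords=pose.coords[order],
            bonds=[(inverse[i], inverse[j], o) for i, j, o in pose.bonds],
            charges=[pose.charges[i] for i in order],
            aromatic=[pose.aromatic[i] for i in order])
        fa = sorted((f.type, tuple(np.round(f.position, 6)))
                    for f in extract_features(pose))
        fb = sorted((f.type, tuple(np.round(f.position, 6)))
                    for f in extract_features(reordered))
        assert fa == fb


class TestPam:
    def test_two_pairs_1d(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [10.0, 0, 0],
                        [11.0, 0, 0]])
        dist = feature_distance_matrix(pts, np.ones(4))
        medoids, assignment, cost = pam_kmedoids(dist, 2)
        assert cost == pytest.approx(2.0)
        assert len(set(medoids) & {0, 1}) == 1
        assert len(set(medoids) & {2, 3}) == 1

    def test_k_equals_n(self):
        pts = np.random.default_rng(1).normal(size=(5, 3))
        dist = feature_distance_matrix(pts, np.ones(5))
        medoids, _, cost = pam_kmedoids(dist, 5)
        assert cost == pytest.approx(0.0)
        assert medoids == [0, 1, 2, 3, 4]

    def test_k1_on_three_points(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        dist = feature_distance_matrix(pts, np.ones(3))
        medoids, _, cost = pam_kmedoids(dist, 1)
        assert medoids == [1]
        assert cost == pytest.approx(2.0)

    def test_invalid_k(self):
        dist = np.zeros((3, 3))
        with pytest.raises(ValueError):
            pam_kmedoids(dist, 0)
        with pytest.raises(ValueError):
            pam_kmedoids(dist, 4)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_optimum_on_clustered_fixtures(self, seed):
        """Exact optimality on blob-structured data (the fixture class the
        consensus pipeline feeds it), n ≤ 12, k ≤ 3."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 4))
        centers = rng.uniform(-15, 15, size=(k, 3))
        pts, radii = [], []
        n = int(rng.integers(max(4, k), 13))
        for i in range(n):
            c = centers[i % k]
            pts.append(c + rng.normal(0, 0.5, 3))
            radii.append(rng.uniform(0.9, 1.1))
        dist = feature_distance_matrix(np.array(pts), np.array(radii))
        _, _, cost = pam_kmedoids(dist, k)
        best_cost, _ = pam_brute_force(dist, k)
        assert cost == pytest.approx(best_cost, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_local_optimum_on_arbitrary_data(self, seed):
        """BUILD+SWAP guarantees a single-swap local optimum (the global
        optimum is not guaranteed for adversarial point sets — that is a
        property of the algorithm itself)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        k = int(rng.integers(1, 4))
        pts = rng.uniform(-5, 5, size=(n, 3))
        dist = feature_distance_matrix(pts, rng.uniform(0.5, 2.0, size=n))
        medoids, _, cost = pam_kmedoids(dist, k)
        best_cost, _ = pam_brute_force(dist, k)
        assert cost >= best_cost - 1e-9
        for mi in range(k):
            for cand in range(n):
                if cand in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = cand
                assert float(dist[:, trial].min(axis=1).sum()) \
                    >= cost - 1e-9

    def test_size_term_in_metric(self):
        pts = np.zeros((2, 3))
        dist = feature_distance_matrix(pts, np.array([1.0, 3.0]),
                                       size_weight=1.0)
        assert dist[0, 1] == pytest.approx(2.0)
        dist = feature_distance_matrix(pts, np.array([1.0, 3.0]),
                                       size_weight=0.5)
        assert dist[0, 1] == pytest.approx(1.0)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 3))
        dist = feature_distance_matrix(pts, np.ones(12))
        a = pam_kmedoids(dist, 3)
        b = pam_kmedoids(dist, 3)
        assert a[0] == b[0]
        assert np.array_equal(a[1], b[1])


class TestChooseK:
    def test_two_blobs(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 0.3, (10, 3)),
                         rng.normal([12, 0, 0], 0.3, (10, 3))])
        dist = feature_distance_matrix(pts, np.ones(20))
        assert choose_k(dist) == 2

    def test_one_blob_falls_back(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 0.3, (10, 3))
        dist = feature_distance_matrix(pts, np.ones(10))
        assert choose_k(dist) == 1

    def test_n2_returns_1(self):
        dist = feature_distance_matrix(np.zeros((2, 3)), np.ones(2))
        assert choose_k(dist) == 1

    def test_n1_rejected(self):
        with pytest.raises(ValueError):
            choose_k(np.zeros((1, 1)))

    def test_three_blobs(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal([0, 0, 0], 0.3, (8, 3)),
                         rng.normal([12, 0, 0], 0.3, (8, 3)),
                         rng.normal([0, 10, 0], 0.3, (8, 3))])
        dist = feature_distance_matrix(pts, np.ones(24))
        assert choose_k(dist) == 3


class TestConsensus:
    def test_planted_types_and_centroids(self, pose_library):
        pose_set, truth = pose_library
        receptor, _ = seven_tm_bundle()
        model = build_consensus(pose_set, receptor)
        got = sorted(e.type for e in model.elements)
        assert got == ["Arm", "NIn"]
        for e in model.elements:
            planted = next(c["centroid"] for c in truth["clusters"]
                           if e.type in c["feature_types"])
            assert np.linalg.norm(e.centroid - planted) <= 0.5

    def test_support_counts_ligands(self, pose_library):
        pose_set, truth = pose_library
        model = build_consensus(pose_set, None)
        for e in model.elements:
            assert e.support == 10
        assert model.elements == sorted(model.elements,
                                        key=lambda e: -e.support)

    def test_annotation_radius_rule(self, bundle):
        ca = bundle.atoms[0].coord
        near = annotate_residues(bundle, ca + np.array([4.0, 0, 0]),
                                 radius=5.0)
        far = annotate_residues(bundle, ca + np.array([6.0, 0, 0]),
                                radius=5.0)
        first = f"A{bundle.atoms[0].resid}"
        assert first in near
        # at 6 Å the first atom itself is out of range
        assert all(not r == first for r in far) or \
            np.linalg.norm(bundle.coords
                           - (ca + np.array([6.0, 0, 0])), axis=1).min() <= 5

    def test_min_support_prunes_all(self, pose_library):
        pose_set, _ = pose_library
        with pytest.warns(UserWarning, match="empty"):
            model = build_consensus(pose_set, None, min_support=999)
        assert model.elements == []

    def test_empty_poses_rejected(self):
        with pytest.raises(ValueError, match="no poses"):
            build_consensus(PoseSet(poses=[]), None)

    def test_residues_table_layout(self, pose_library):
        pose_set, _ = pose_library
        receptor, _ = seven_tm_bundle()
        model = build_consensus(pose_set, receptor)
        df = model.residues_table()
        assert list(df.columns) == [
            "element_type", "centroid_x", "centroid_y", "centroid_z",
            "radius", "support", "residues_within_5A"]

    def test_json_roundtrip(self, tmp_path, pose_library):
        import json
        pose_set, _ = pose_library
        model = build_consensus(pose_set, None)
        model.to_json(tmp_path / "m.json")
        data = json.loads((tmp_path / "m.json").read_text())
        assert data["n_ligands"] == 20
        assert len(data["elements"]) == len(model.elements)


class TestCompareModels:
    def _model(self, elements):
        from gpcrkit.pharmacophore import ConsensusElement
        return ConsensusModel(
            elements=[ConsensusElement(type=t, centroid=np.asarray(c,
                                                                   float),
                                       radius=1.0, support=5)
                      for t, c in elements],
            n_ligands=5, min_support=1, annotation_radius=5.0)

    def test_self_comparison(self):
        m = self._model([("Arm", [0, 0, 0]), ("HAc", [5, 0, 0])])
        rep = compare_models(m, m, match_radius=2.0)
        assert (rep.status == "matched").all()
        assert rep.centroid_shift.max() == pytest.approx(0.0)

    def test_disjoint_types(self):
        a = self._model([("Arm", [0, 0, 0])])
        b = self._model([("NIn", [0, 0, 0])])
        rep = compare_models(a, b, match_radius=2.0)
        assert set(rep.status) == {"only_a", "only_b"}

    def test_translated_shift(self):
        a = self._model([("Arm", [0, 0, 0]), ("HAc", [5, 0, 0])])
        b = self._model([("Arm", [1, 0, 0]), ("HAc", [6, 0, 0])])
        rep = compare_models(a, b, match_radius=2.0)
        matched = rep[rep.status == "matched"]
        assert len(matched) == 2
        assert np.allclose(matched.centroid_shift, 1.0, atol=1e-6)


class TestPoseSetUtils:
    def test_pki_filter(self, pose_library):
        pose_set, _ = pose_library
        narrow = pose_set.filter_pki(6.0, 7.0)
        for p in narrow:
            assert 6.0 <= p.pki <= 7.0

    def test_sdf_roundtrip(self, tmp_path, pose_library):
        from gpcrkit.poses import read_sdf, write_sdf
        pose_set, _ = pose_library
        path = tmp_path / "lib.sdf"
        write_sdf(pose_set, path)
        back = read_sdf(path)
        assert len(back) == len(pose_set)
        for a, b in zip(pose_set, back):
            assert a.ligand_id == b.ligand_id
            assert a.pose_id == b.pose_id
            assert a.elements == b.elements
            assert np.abs(a.coords - b.coords).max() < 1e-3
            assert a.charges == b.charges
            assert b.pki == pytest.approx(a.pki, abs=1e-3)
        # features survive the round trip
        fa = extract_features(pose_set.poses[0])
        fb = extract_features(back.poses[0])
        assert [f.type for f in fa] == [f.type for f in fb]
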