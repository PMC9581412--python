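"""Distance features: arithmetic examples, brute-force oracles, invariances."""

import numpy as np
import pytest

import ligandmsm as lm
from ligandmsm import DataError, EmptyFeatureError, ParameterError, TopologyError
from ligandmsm.featurization import Topology, TrajectoryEnsemble, residue_min_distances


def make_traj(coords, atom_names, residue_ids, is_ligand, spacing=1.0):
    top = Topology(atom_names, np.asarray(residue_ids), np.asarray(is_ligand))
    return TrajectoryEnsemble(top, [np.asarray(coords, float)], spacing)


@pytest.fixture()
def two_residue_traj():
    # residue 0: two atoms; residue 1: one atom; ligand: one atom
    coords = np.array([[[0, 0, 0], [1, 0, 0], [0, 3, 0], [3, 0, 0]]], dtype=float)
    return make_traj(coords, ["CA", "CB", "CA", "L1"], [0, 0, 1, 2],
                     [False, False, False, True])


class TestMinDistance:
    def test_minimum_over_residue_atoms(self, two_residue_traj):
        d = lm.min_distance_matrix(two_residue_traj, ligand_atoms=["L1"])[0]
        assert d.shape == (1, 2, 1)
        assert np.isclose(d[0, 0, 0], 2.0)  # min(3, 2)
        assert np.isclose(d[0, 1, 0], np.sqrt(9 + 9))

    def test_missing_identifier_raises(self, two_residue_traj):
        with pytest.raises(TopologyError, match="L9"):
            lm.min_distance_matrix(two_residue_traj, ligand_atoms=["L9"])
        with pytest.raises(TopologyError):
            lm.min_distance_matrix(two_residue_traj, residue_range=(0, 5),
                                   ligand_atoms=["L1"])

    def test_reference_configuration_feature_count(self):
        """60 residues × 5 ligand atoms gives 300 features per frame."""
        rng = np.random.default_rng(0)
        n_res = 60
        lig_names = ["C25", "C24", "C10", "SC4", "C16"]
        names = ["CA"] * n_res + lig_names
        resids = list(range(88, 148)) + [200] * 5
        is_lig = [False] * n_res + [True] * 5
        coords = rng.normal(0, 10, size=(3, n_res + 5, 3))
        traj = make_traj(coords, names, resids, is_lig)
        spec = lm.FeatureSpec("ligand_contacts", "inverse", 6.0, lig_names, (88, 147))
        fs = lm.featurize_ligand_contacts(traj, spec)
        assert fs.n_features == 300

    def test_matches_brute_force_enumeration(self):
        """Minimum over 5-atom residues equals the exhaustive all-pair minimum."""
        rng = np.random.default_rng(1)
        n_res, atoms_per, n_lig, n_frames = 4, 5, 3, 6
        n_prot = n_res * atoms_per
        coords = rng.normal(0, 8, size=(n_frames, n_prot + n_lig, 3))
        names = [f"A{i}" for i in range(n_prot)] + [f"L{a}" for a in range(n_lig)]
        resids = list(np.repeat(np.arange(n_res), atoms_per)) + [99] * n_lig
        is_lig = [False] * n_prot + [True] * n_lig
        traj = make_traj(coords, names, resids, is_lig)
        d = lm.min_distance_matrix(traj, ligand_atoms=[f"L{a}" for a in range(n_lig)])[0]
        for t in range(n_frames):
            for r in range(n_res):
                for a in range(n_lig):
                    brute = min(
                        np.linalg.norm(coords[t, r * atoms_per + i] - coords[t, n_prot + a])
                        for i in range(atoms_per)
                    )
                    assert np.isclose(d[t, r, a], brute, atol=1e-12)


class TestQuasiBinaryTransform:
    @pytest.mark.parametrize(
        "d,transform,cutoff,expected",
        [
            (3.0, "inverse", 6.0, 1 / 3),
            (6.5, "inverse", 6.0, 0.0),
            (6.5, "binary", 6.0, 0.0),
            (5.0, "binary", 6.0, 1.0),
        ],
    )
    def test_pointwise(self, d, transform, cutoff, expected):
        spec = lm.FeatureSpec("ligand_contacts", transform, cutoff, ["L1"])
        fs = lm.transform_quasibinary([np.full((1, 1, 1), d)], spec)
        assert np.isclose(fs.matrices[0][0, 0], expected)

    def test_nonpositive_distance_rejected(self):
        spec = lm.FeatureSpec("ligand_contacts", "inverse", 6.0, ["L1"])
        with pytest.raises(DataError):
            lm.transform_quasibinary([np.zeros((1, 1, 1))], spec)

    def test_bounds(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(0.5, 12.0, size=(50, 4, 2))
        for transform in ("binary", "inverse"):
            spec = lm.FeatureSpec("ligand_contacts", transform, 6.0, ["L1", "L2"])
            fs = lm.transform_quasibinary([d], spec)
            m = fs.matrices[0]
            assert (m >= 0).all()
            if transform == "binary":
                assert set(np.unique(m)) <= {0.0, 1.0}
            else:
                assert (m <= 1 / d.reshape(50, -1)).all()


class TestResiduePairFeatures:
    def test_threshold_crossing_filter(self):
        # pair 0 fixed at 4 Å (never crosses); pair 1 alternates 5 / 8 Å
        d = np.array([[4.0, 5.0], [4.0, 8.0], [4.0, 5.0]])
        fs = lm.build_residue_pair_features(
            distances=[d], pair_labels=[(1, 2), (1, 3)], cutoff_filter=6.5
        )
        assert fs.labels == [(1, 3)]
        assert np.allclose(fs.matrices[0][:, 0], [0.2, 0.125, 0.2])

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(3.0, 10.0, size=(40, 15))
        labels = [(i, i + 20) for i in range(15)]
        fs = lm.build_residue_pair_features(
            distances=[d], pair_labels=labels, cutoff_filter=6.5
        )
        kept = []
        for j in range(15):
            col = d[:, j]
            if (col < 6.5).any() and (col > 6.5).any():
                kept.append(labels[j])
        assert fs.labels == kept

    def test_empty_retained_set_raises(self):
        d = np.full((10, 3), 4.0)
        with pytest.raises(EmptyFeatureError):
            lm.build_residue_pair_features(
                distances=[d], pair_labels=[(0, 1), (0, 2), (1, 2)], cutoff_filter=6.5
            )

    def test_from_trajectory(self, toy_complex):
        _, traj, _ = toy_complex
        fs = lm.build_residue_pair_features(traj, cutoff_filter=6.5)
        assert fs.n_features > 0
        assert all(len(lab) == 2 for lab in fs.labels)
        # values are plain inverse distances: all strictly positive
        assert all((m > 0).all() for m in fs.matrices)


class TestExternalStructure:
    def test_consistency_with_trajectory_frame(self, toy_complex):
        _, traj, _ = toy_complex
        lig = [traj.topology.atom_names[i]
               for i in np.flatnonzero(traj.topology.is_ligand)]
        spec = lm.FeatureSpec("ligand_contacts", "inverse", 6.0, lig)
        fs = lm.featurize_ligand_contacts(traj, spec)
        v = lm.featurize_external_structure(traj.frame(0, 17), spec)
        assert np.allclose(v, fs.matrices[0][17])

    def test_rigid_motion_invariance(self, toy_complex):
        _, traj, _ = toy_complex
        lig = [traj.topology.atom_names[i]
               for i in np.flatnonzero(traj.topology.is_ligand)]
        spec = lm.FeatureSpec("ligand_contacts", "inverse", 6.0, lig)
        frame = traj.frame(0, 5)
        v0 = lm.featurize_external_structure(frame, spec)
        # translation
        shifted = TrajectoryEnsemble(
            traj.topology, [frame.coords[0] + np.array([10.0, -4.0, 2.0])]
        )
        assert np.allclose(lm.featurize_external_structure(shifted, spec), v0)
        # random proper rotation (via QR with determinant fix)
        rng = np.random.default_rng(4)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        rotated = TrajectoryEnsemble(traj.topology, [frame.coords[0] @ Q])
        assert np.allclose(lm.featurize_external_structure(rotated, spec), v0, atol=1e-9)

    def test_multi_frame_input_rejected(self, toy_complex):
        _, traj, _ = toy_complex
        lig = [traj.topology.atom_names[i]
               for i in np.flatnonzero(traj.topology.is_ligand)]
        spec = lm.FeatureSpec("ligand_contacts", "inverse", 6.0, lig)
        with pytest.raises(ParameterError):
            lm.featurize_external_structure(traj, spec)


class TestIO:
    def test_feature_roundtrip(self, tmp_path, toy_complex):
        _, traj, _ = toy_complex
        fs = lm.build_residue_pair_features(traj, cutoff_filter=6.5)
        fs.save(str(tmp_path / "feat"))
        loaded = lm.FeatureSet.load(str(tmp_path / "feat"))
        assert loaded.labels == fs.labels
        for a, b in zip(loaded.matrices, fs.matrices):
            assert np.allclose(a, b)

    def test_pdb_writer_roundtrips_coordinates(self, tmp_path, toy_complex):
        _, traj, _ = toy_complex
        single = traj.frame(0, 0)
        path = tmp_path / "frame.pdb"
        single.write_pdb(str(path))
        text = path.read_text()
        assert text.count("MODEL") == 1
        # parse coordinates back out of the fixed-width columns
        xyz = np.array([
            [float(l[30:38]), float(l[38:46]), float(l[46:54])]
            for l in text.splitlines() if l.startswith("ATOM")
        ])
        assert np.allclose(xyz, single.coords[0][0], atol=1e-3)

    def test_hydrogens_excluded_from_pair_distances(self):
        # residue 0 has a hydrogen closer to residue 1 than any heavy atom
        coords = np.array([[[0, 0, 0], [2.0, 0, 0], [5.0, 0, 0], [9, 9, 9]]], float)
        traj = make_traj(coords, ["CA", "H1", "CA", "L1"], [0, 0, 1, 2],
                         [False, False, False, True])
        d, labels = residue_min_distances(traj, exclude_neighbors=0)
        assert labels == [(0, 1)]
        assert np.isclose(d[0][0, 0], 5.0)  # heavy-heavy, not 3.0 via H
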