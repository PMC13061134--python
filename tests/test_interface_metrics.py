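"""Superposition, TM-score, interface extraction and merged DockQ."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from abageval.frames_ae import ae_scores, aligned_error_matrix
from abageval.interface_metrics import (dockq_from_components, dockq_merged,
                                        interface_residues, superpose,
                                        tm_score)
from abageval.structure_io import StructureModel, partition_complex
from abageval.synthetic import (make_decoy, make_toy_complex, random_rotation)


class TestSuperpose:
    def test_identical_sets_identity_transform(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        rot, trans, rmsd = superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, 0.0, atol=1e-10)
        assert rmsd < 1e-10

    def test_recovers_known_rigid_motion(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        rot_true = random_rotation(rng)
        t_true = rng.normal(size=3) * 10
        target = pts @ rot_true.T + t_true
        rot, trans, rmsd = superpose(pts, target)
        np.testing.assert_allclose(rot, rot_true, atol=1e-8)
        np.testing.assert_allclose(trans, t_true, atol=1e-8)
        assert rmsd < 1e-8

    def test_mirror_image_never_reflected(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(15, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        rot, _, rmsd = superpose(pts, mirrored)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestTmScore:
    def test_identical_structures_score_one(self, toy_complex):
        assert tm_score(toy_complex, toy_complex) == pytest.approx(1.0,
                                                                   abs=1e-9)

    def test_invariant_under_global_rigid_motion(self, toy_complex,
                                                 decoy_factory):
        decoy = decoy_factory(6.0, seed=5, jitter=0.5)
        base = tm_score(decoy, toy_complex)
        rng = np.random.default_rng(3)
        moved = decoy.transformed(random_rotation(rng),
                                  rng.normal(scale=25.0, size=3))
        assert tm_score(moved, toy_complex) == pytest.approx(base, abs=1e-6)

    def test_matches_direct_optimization_oracle_on_small_toy(self):
        """The iterative-superposition heuristic agrees with multi-start
        direct optimization of the TM objective over all rigid motions."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        from abageval.frames_ae import tm_weight

        query = make_toy_complex([20], seed=6, chain_ids=["Q"])
        rng = np.random.default_rng(7)
        reference = make_toy_complex([20], seed=6, chain_ids=["Q"])
        # decoy with a hinge: second half rigidly rotated, plus mild jitter
        hinge = random_rotation(np.random.default_rng(1))
        pivot = reference.chains[0].residues[10].ca_xyz.copy()
        for i, res in enumerate(reference.chains[0].residues):
            def move(p, i=i):
                p = p + rng.normal(scale=0.2, size=3)
                return hinge @ (p - pivot) + pivot if i >= 10 else p

            res.ca_xyz = move(res.ca_xyz)
            res.n_xyz = move(res.n_xyz)
            res.c_xyz = move(res.c_xyz)
            res.heavy_atoms = [(nm, move(p)) for nm, p in res.heavy_atoms]
        x = query.ca_coords()
        y = reference.ca_coords()
        n = len(x)

        def objective(params):
            rot = Rotation.from_rotvec(params[:3]).as_matrix()
            d = np.linalg.norm(x @ rot.T + params[3:] - y, axis=1)
            return -float(tm_weight(d, n).mean())

        best = 0.0
        for k in range(40):
            rotvec = rng.normal(size=3) * (0.0 if k == 0 else rng.uniform(0, np.pi))
            rot0 = Rotation.from_rotvec(rotvec).as_matrix()
            t0 = y.mean(axis=0) - rot0 @ x.mean(axis=0)
            res = minimize(objective, np.concatenate([rotvec, t0]),
                           method="Nelder-Mead",
                           options={"maxiter": 2000, "xatol": 1e-8,
                                    "fatol": 1e-12})
            best = max(best, -res.fun)
        value = tm_score(query, reference)
        assert value == pytest.approx(best, abs=0.01)

    def test_degrades_with_noise(self, toy_complex, toy_partition):
        scores = []
        for sigma in (0.2, 1.0, 3.0):
            noisy = make_decoy(toy_complex, toy_partition,
                               jitter_sigma=sigma, seed=9)
            scores.append(tm_score(noisy, toy_complex))
        assert scores[0] > scores[1] > scores[2]

    def test_upper_bounds_ae_tm(self, toy_complex, decoy_factory):
        for seed in range(5):
            decoy = decoy_factory(4.0 + seed, seed=seed, jitter=0.3)
            sc = ae_scores(aligned_error_matrix(decoy, toy_complex))
            assert tm_score(decoy, toy_complex) >= sc.ae_tm - 1e-6


class TestInterfaceResidues:
    def test_distant_groups_have_empty_interface(self):
        apart = make_toy_complex([10, 10], separation=50.0, seed=1,
                                 chain_ids=["H", "A"])
        part = partition_complex(apart, ["H"], ["A"])
        assert interface_residues(apart, part, 12.0) == set()

    def test_threshold_semantics(self, toy_complex, toy_partition):
        at12 = interface_residues(toy_complex, toy_partition, 12.0)
        at10 = interface_residues(toy_complex, toy_partition, 10.0)
        assert at10 <= at12
        assert len(at12) > 0

    def test_matches_brute_force_all_pairs(self, toy_complex, toy_partition):
        cutoff = 8.0
        expected = set()
        ab = [(c.chain_id, r) for c in toy_complex.chains
              if c.chain_id == "H" for r in c.residues]
        ag = [(c.chain_id, r) for c in toy_complex.chains
              if c.chain_id == "A" for r in c.residues]
        for cid_a, ra in ab:
            for cid_b, rb in ag:
                d = cdist(np.array([x for _, x in ra.heavy_atoms]),
                          np.array([x for _, x in rb.heavy_atoms]))
                if d.min() <= cutoff:
                    expected.add((cid_a, ra.res_number, ra.insertion_code))
                    expected.add((cid_b, rb.res_number, rb.insertion_code))
        assert interface_residues(toy_complex, toy_partition,
                                  cutoff) == expected


class TestDockQ:
    def test_closed_form_combination(self):
        assert dockq_from_components(0.5, 1.5, 8.5) == pytest.approx(0.5,
                                                                     abs=1e-15)
        assert dockq_from_components(1.0, 0.0, 0.0) == 1.0

    def test_identical_structures_score_one(self, toy_complex, toy_partition):
        res = dockq_merged(toy_complex, toy_complex, toy_partition)
        assert res.fnat == 1.0
        assert res.irms == pytest.approx(0.0, abs=1e-9)
        assert res.lrms == pytest.approx(0.0, abs=1e-9)
        assert res.dockq == pytest.approx(1.0, abs=1e-12)
        assert res.native_contacts > 0

    def test_invariant_under_rigid_motion_of_query(self, toy_complex,
                                                   toy_partition):
        rng = np.random.default_rng(13)
        moved = toy_complex.transformed(random_rotation(rng),
                                        rng.normal(scale=30.0, size=3))
        res = dockq_merged(moved, toy_complex, toy_partition)
        assert res.dockq == pytest.approx(1.0, abs=1e-9)

    def test_displaced_antigen_scores_near_zero(self, toy_complex,
                                                toy_partition):
        decoy = make_decoy(toy_complex, toy_partition,
                           translation=np.array([0.0, 40.0, 0.0]))
        res = dockq_merged(decoy, toy_complex, toy_partition)
        assert res.fnat == 0.0
        assert res.dockq < 0.1

    def test_antigen_concatenation_order_irrelevant(self, three_chain_complex):
        part = partition_complex(three_chain_complex, ["H"], ["A", "B"])
        decoy = make_decoy(three_chain_complex, part,
                           translation=np.array([1.0, 2.0, 0.5]))
        direct = dockq_merged(decoy, three_chain_complex, part)
        swapped_q = StructureModel(
            "q", [decoy.chains[0], decoy.chains[2], decoy.chains[1]])
        swapped_r = StructureModel(
            "r", [three_chain_complex.chains[0], three_chain_complex.chains[2],
                  three_chain_complex.chains[1]])
        swapped = dockq_merged(swapped_q, swapped_r, part)
        assert swapped.dockq == pytest.approx(direct.dockq, abs=1e-9)
        assert swapped.fnat == direct.fnat
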