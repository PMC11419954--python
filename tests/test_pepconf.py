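"""Conformation engine: loss composition, FAPE behaviour, distograms,
frames, forward determinism, atom realization and training mechanics."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from neoasurf import autodiff as ad
from neoasurf import chemdata, fixtures, pepconf, structure
from neoasurf.autodiff import Tensor
from neoasurf.pepconf import (FAPE_CLAMP, FAPE_SCALE, ModelConfig,
                              PepConfError, PepConfModel)


@pytest.fixture(scope="module")
def toy_setup():
    hla = fixtures.make_groove(fixtures.GrooveSpec(seed=3))
    pep = fixtures.make_arch_peptide(fixtures.ArchSpec(seed=3))
    padded = structure.pad_peptide(pep.sequence)
    return hla, padded, pep


class TestLossComposition:
    def test_fixed_weights_forced_by_all_ones(self):
        bd, _ = pepconf.total_loss(1, 1, 1, 1, 1, 1)
        assert bd.pep == pytest.approx(3.3)
        assert bd.phla == pytest.approx(10.0)
        assert bd.total == pytest.approx(13.3)

    def test_zero_and_single_term(self):
        assert pepconf.total_loss(0, 0, 0, 0, 0, 0)[0].total == 0.0
        assert pepconf.total_loss(0.5, 0, 0, 0, 0, 0)[0].total == pytest.approx(0.5)

    def test_identities_hold_exactly_for_random_losses(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            parts = rng.uniform(0, 10, 6)
            bd, _ = pepconf.total_loss(*parts)
            assert bd.pep == bd.fape + 0.3 * bd.dist + bd.angle + bd.viol
            assert bd.phla == 9.5 * bd.phla_fape + 0.5 * bd.phla_dist
            assert bd.total == bd.pep + bd.phla

    def test_negative_losses_rejected(self):
        with pytest.raises(PepConfError):
            pepconf.total_loss(-0.1, 0, 0, 0, 0, 0)


class TestFrames:
    def test_rotations_are_proper(self, toy_setup):
        _, _, pep = toy_setup
        for f in pepconf.frames_of_chain(pep):
            assert np.linalg.det(f.rotation) == pytest.approx(1.0, abs=1e-10)
            np.testing.assert_allclose(f.rotation @ f.rotation.T, np.eye(3),
                                       atol=1e-10)

    def test_collinear_backbone_rejected(self):
        N = np.array([[0.0, 0, 0]])
        CA = np.array([[1.0, 0, 0]])
        C = np.array([[2.0, 0, 0]])
        with pytest.raises(PepConfError):
            pepconf.gram_schmidt_frames(N, CA, C)


class TestFAPE:
    def rigid(self, seed):
        rng = np.random.default_rng(seed)
        R = Rotation.random(rng=rng).as_matrix()
        return R, rng.uniform(-10, 10, 3)

    def test_identity_is_zero(self, toy_setup):
        _, _, pep = toy_setup
        frames = pepconf.frames_of_chain(pep)
        atoms = pep.atom_coords()
        assert float(pepconf.fape(frames, atoms, frames, atoms).data) == \
            pytest.approx(0.0, abs=1e-6)  # eps-stabilized norm floor

    def test_joint_rigid_invariance(self, toy_setup):
        _, _, pep = toy_setup
        frames = pepconf.frames_of_chain(pep)
        atoms = pep.atom_coords()
        R, t = self.rigid(1)
        moved = pepconf.frames_of_chain(pep.transformed(R, t))
        assert float(pepconf.fape(moved, atoms @ R.T + t, frames, atoms).data
                     ) == pytest.approx(0.0, abs=1e-6)

    def test_one_frame_one_atom_hand_value(self):
        frame = (np.eye(3)[None], np.zeros((1, 3)))
        pred = np.array([[2.0, 0.0, 0.0]])
        true = np.array([[0.0, 0.0, 0.0]])
        # local error 2 A -> min(10, 2)/10 = 0.2
        assert float(pepconf.fape(frame, pred, frame, true).data) == \
            pytest.approx(0.2)

    def test_phla_fape_detects_peptide_translation(self, toy_setup):
        hla, _, pep = toy_setup
        hla_frames = pepconf.frames_of_chain(hla)
        atoms = pep.atom_coords()
        shift2 = atoms + np.array([0, 0, 2.0])
        assert float(pepconf.phla_fape(hla_frames, shift2, atoms).data) == \
            pytest.approx(2.0 / FAPE_SCALE, abs=1e-9)
        far = atoms + np.array([0, 0, 200.0])
        assert float(pepconf.phla_fape(hla_frames, far, atoms).data) == \
            pytest.approx(FAPE_CLAMP / FAPE_SCALE)

    def test_intra_fape_invariant_where_phla_is_not(self, toy_setup):
        _, _, pep = toy_setup
        shift = np.array([0, 0, 2.0])
        moved = pep.transformed(np.eye(3), shift)
        pep_frames = pepconf.frames_of_chain(pep)
        moved_frames = pepconf.frames_of_chain(moved)
        intra = pepconf.fape(moved_frames, moved.atom_coords(),
                             pep_frames, pep.atom_coords())
        assert float(intra.data) == pytest.approx(0.0, abs=1e-6)


class TestDistogram:
    def test_one_hot_logits_near_zero_loss(self):
        d = np.array([[0.0, 5.0], [5.0, 0.0]])
        bins = pepconf.distance_bins(d)
        logits = np.full((2, 2, 64), -50.0)
        for i in range(2):
            for j in range(2):
                logits[i, j, bins[i, j]] = 50.0
        assert float(pepconf.distogram_loss(Tensor(logits), d).data) == \
            pytest.approx(0.0, abs=1e-10)

    def test_uniform_logits_log_bins(self):
        d = np.random.default_rng(0).uniform(2, 20, (3, 3))
        loss = pepconf.distogram_loss(Tensor(np.zeros((3, 3, 64))), d)
        assert float(loss.data) == pytest.approx(np.log(64))

    def test_hand_computed_three_pairs(self):
        d = np.array([1.0, 10.0, 30.0])  # bins 0, mid, last
        bins = pepconf.distance_bins(d)
        assert bins[0] == 0 and bins[2] == 63
        logits = np.zeros((3, 1, 64))
        logits[:, :, 0] = 1.0  # favour bin 0 for every pair
        logZ = np.log(np.exp(1.0) + 63)
        picked = [logits[k, 0, bins[k]] for k in range(3)]
        expected = -np.mean([p - logZ for p in picked])
        loss = pepconf.distogram_loss(Tensor(logits), d.reshape(3, 1))
        assert float(loss.data) == pytest.approx(expected)

    def test_nan_logits_rejected(self):
        with pytest.raises(PepConfError):
            pepconf.distogram_loss(Tensor(np.full((2, 2, 64), np.nan)),
                                   np.zeros((2, 2)))


class TestTorsionAndViolation:
    def test_exact_angles_zero_loss(self):
        ang = np.array([[0.3, -1.2], [2.0, 0.1]])
        pred = np.stack([np.cos(ang), np.sin(ang)], axis=-1)
        loss = pepconf.torsion_angle_loss(Tensor(pred), ang)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-12)

    def test_norm_penalty_for_unnormalized(self):
        ang = np.zeros((1, 1))
        pred = np.array([[[2.0, 0.0]]])  # right direction, wrong norm
        loss = pepconf.torsion_angle_loss(Tensor(pred), ang)
        assert float(loss.data) == pytest.approx(0.02 * 1.0)

    def build_ideal_extended(self, n=5):
        N, CA, C = [np.zeros(3)], [], []
        CA.append(N[0] + np.array([chemdata.BOND_N_CA, 0, 0]))
        ang = np.deg2rad(180 - chemdata.ANGLE_N_CA_C)
        C.append(CA[0] + chemdata.BOND_CA_C *
                 np.array([np.cos(ang), np.sin(ang), 0]))
        for i in range(1, n):
            N.append(chemdata.place_atom(N[i - 1], CA[i - 1], C[i - 1],
                                         chemdata.BOND_C_N,
                                         chemdata.ANGLE_CA_C_N, 180.0))
            CA.append(chemdata.place_atom(CA[i - 1], C[i - 1], N[i],
                                          chemdata.BOND_N_CA,
                                          chemdata.ANGLE_C_N_CA, 180.0))
            C.append(chemdata.place_atom(C[i - 1], N[i], CA[i],
                                         chemdata.BOND_CA_C,
                                         chemdata.ANGLE_N_CA_C, 180.0))
        return np.array(N), np.array(CA), np.array(C)

    def test_ideal_extended_backbone_has_no_violations(self):
        N, CA, C = self.build_ideal_extended()
        loss = pepconf.violation_loss(Tensor(N), Tensor(CA), Tensor(C))
        assert float(loss.data) == pytest.approx(0.0, abs=1e-12)

    def test_clash_penalty_grows_as_atoms_approach(self):
        N, CA, C = self.build_ideal_extended()
        vals = []
        for gap in (1.5, 1.0, 0.5):
            N2 = N.copy()
            # drag the last residue's N near the first residue's CA
            N2[-1] = CA[0] + np.array([gap, 0, 0])
            vals.append(float(pepconf.violation_loss(
                Tensor(N2), Tensor(CA), Tensor(C)).data))
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] > 0


class TestPHLADistanceMatrix:
    def test_toy_matches_brute_force(self, toy_setup):
        hla, _, pep = toy_setup
        D, mask = pepconf.phla_distance_matrix(hla, pep)
        rep_pep = pepconf.representative_coords(pep)
        rep_hla = pepconf.representative_coords(hla)
        coords = np.vstack([rep_pep, rep_hla])
        n_p = len(rep_pep)
        assert D.shape == (16 + 180, 16 + 180)
        # peptide-peptide block
        for i in range(n_p):
            for j in range(n_p):
                assert D[i, j] == pytest.approx(
                    np.linalg.norm(coords[i] - coords[j]))
        # PAD rows zeroed and masked
        assert not mask[n_p:16].any()
        assert np.all(D[n_p:16] == 0)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)


class TestForward:
    def test_deterministic_under_seed(self, toy_setup):
        hla, padded, _ = toy_setup
        cfg = ModelConfig(h=len(hla), seed=11)
        p1 = pepconf.forward(cfg, hla, padded)
        p2 = pepconf.forward(cfg, hla, padded)
        np.testing.assert_array_equal(p1.ca_coords(), p2.ca_coords())
        np.testing.assert_array_equal(p1.plddt.per_residue,
                                      p2.plddt.per_residue)

    def test_pad_positions_emit_no_atoms(self, toy_setup):
        hla, padded, _ = toy_setup
        cfg = ModelConfig(h=len(hla), seed=1)
        pred = pepconf.forward(cfg, hla, padded)
        assert len(pred.atoms) == padded.true_length

    @pytest.mark.parametrize("seq", ["GGGGGGG", "WKRFYAC", "ADQHILMNPSTV"])
    def test_atom_count_matches_residue_topology(self, toy_setup, seq):
        hla, _, _ = toy_setup
        cfg = ModelConfig(h=len(hla), seed=2)
        pred = pepconf.forward(cfg, hla, structure.pad_peptide(seq))
        expected = sum(chemdata.heavy_atom_count(chemdata.ONE_TO_THREE[c])
                       for c in seq)
        assert pred.n_atoms == expected
        for rn, atoms in zip(pred.residue_names, pred.atoms):
            assert sorted(atoms) == sorted(chemdata.heavy_atom_names(rn))

    def test_plddt_in_range(self, toy_setup):
        hla, padded, _ = toy_setup
        pred = pepconf.forward(ModelConfig(h=len(hla), seed=3), hla, padded)
        assert np.all((pred.plddt.per_residue >= 0)
                      & (pred.plddt.per_residue <= 100))


class TestTrainingMechanics:
    def small_config(self, hla, seed=0):
        return ModelConfig(h=len(hla), d=16, n_blocks=1, seed=seed)

    def test_gradient_check_on_three_residue_toy(self):
        hla = fixtures.make_groove(fixtures.GrooveSpec(seed=5))
        pep = fixtures.make_arch_peptide(
            fixtures.ArchSpec(length=3, bulge_height=4.0, seed=5))
        padded = structure.pad_peptide(pep.sequence)
        cfg = ModelConfig(h=len(hla), d=8, n_blocks=1, seed=5)
        model = PepConfModel(cfg)
        params = model.parameters()

        def loss_value():
            _, total = pepconf.example_losses(model, hla, padded, pep)
            return total

        total = loss_value()
        total.backward()
        rng = np.random.default_rng(0)
        checked = 0
        for p in params:
            if p.grad is None or p.data.size > 400:
                continue
            flat_idx = rng.choice(p.data.size, size=min(3, p.data.size),
                                  replace=False)
            for fi in flat_idx:
                i = np.unravel_index(fi, p.data.shape)
                eps = 1e-5
                p.data[i] += eps
                fp = float(loss_value().data)
                p.data[i] -= 2 * eps
                fm = float(loss_value().data)
                p.data[i] += eps
                num = (fp - fm) / (2 * eps)
                ana = p.grad[i]
                denom = max(abs(num), abs(ana), 1e-3)
                assert abs(num - ana) / denom < 1e-4
                checked += 1
        assert checked >= 20

    def test_zero_steps_leaves_model_unchanged(self, toy_setup):
        hla, padded, pep = toy_setup
        cfg = self.small_config(hla)
        model, curve = pepconf.train_toy(cfg, [(hla, padded, pep)], steps=0)
        reference = PepConfModel(cfg)
        for a, b in zip(model.parameters(), reference.parameters()):
            np.testing.assert_array_equal(a.data, b.data)
        assert curve == []

    def test_zero_learning_rate_flat_curve(self, toy_setup):
        hla, padded, pep = toy_setup
        cfg = self.small_config(hla)
        _, curve = pepconf.train_toy(cfg, [(hla, padded, pep)], steps=5, lr=0.0)
        totals = [bd.total for bd in curve]
        assert max(totals) - min(totals) < 1e-12

    def test_empty_dataset_rejected(self, toy_setup):
        hla, _, _ = toy_setup
        with pytest.raises(PepConfError):
            pepconf.train_toy(self.small_config(hla), [], steps=1)


class TestSelfDistillSelect:
    def make_pred(self, value):
        return pepconf.FoldPrediction(
            residue_names=["GLY"], atoms=[{"CA": np.zeros(3)}],
            plddt=pepconf.PLDDTRecord(np.full(3, value)))

    def test_threshold_and_report(self):
        preds = [self.make_pred(v) for v in (80.0, 92.0, 99.0)]
        kept, report = pepconf.self_distill_select(preds)
        assert [p.plddt.aggregate for p in kept] == [92.0, 99.0]
        assert report == {"total": 3, "retained": 2, "removed": 1,
                          "threshold": 92.0}

    def test_empty_and_identity(self):
        assert pepconf.self_distill_select([])[0] == []
        preds = [self.make_pred(95.0)]
        assert pepconf.self_distill_select(preds)[0] == preds
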