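"""Restraints, pose generation, surrogate scoring, minimization, scans."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from conftest import naive_score
from shiftdock import (
    EnergyReport,
    EnergyWeights,
    Pose,
    RestraintSet,
    Residue,
    Structure,
    build_restraints,
    classify_residues,
    compute_csp,
    decompose_energy,
    gen_structures,
    generate_poses,
    interface_rmsd,
    minimize_pose,
    mutate_and_score,
    random_poses,
    rank_complexes,
    restraint_satisfaction,
    score_pose,
)
from shiftdock.csp import PeakPair
from shiftdock.docking import PoseGenerationError
from shiftdock.structures import random_rotation, rotation_about_axis

IDENTITY = lambda idx=1: Pose(index=idx, rotation=np.eye(3),
                              translation=np.zeros(3))


def two_residue_system(distance=5.0, rec_aa="K", lig_aa="D"):
    """Minimal one-residue-per-chain system at a chosen side-chain distance."""
    receptor = Structure("A", [Residue.make(1, rec_aa, (0, 0, 0), (0, 0, 0))])
    ligand = Structure("B", [Residue.make(1, lig_aa, (distance, 50, 0),
                                          (distance, 0, 0))])
    return receptor, ligand


class TestRestraints:
    def make_profile(self, categories):
        pairs = [PeakPair(number=i + 1, aa="A", delta_h=0.01, delta_n=0.0,
                          int_0=1.0, int_i=1.0) for i in range(len(categories))]
        profile = compute_csp(pairs)
        profile.table["category"] = categories
        return profile

    def test_category_filter_sizes(self):
        receptor_profile = self.make_profile(
            ["red", "red", "orange", "orange", "orange", "below_mean"])
        ligand_profile = self.make_profile(["red", "below_mean", "orange",
                                            "below_mean", "below_mean"])
        rs_red = build_restraints(receptor_profile, ligand_profile, "red")
        assert len(rs_red.active_receptor) == 2
        assert rs_red.active_ligand == {1}
        rs_orange = build_restraints(receptor_profile, ligand_profile, "orange")
        assert len(rs_orange.active_receptor) == 5
        assert rs_orange.active_ligand == {1, 3}

    def test_empty_active_set_suggests_lowering(self):
        a = self.make_profile(["orange"] * 5)
        b = self.make_profile(["below_mean"] * 5)
        with pytest.raises(ValueError, match="min_category"):
            build_restraints(a, b, "red")

    def test_truth_pose_full_satisfaction(self, planted_complex,
                                          planted_restraints):
        receptor, ligand, truth = planted_complex
        frac, flags = restraint_satisfaction(
            receptor, ligand, truth.planted_pose, planted_restraints)
        assert frac == 1.0
        assert all(flags.values())

    def test_tsv_round_trip(self, tmp_path, planted_restraints):
        path = tmp_path / "restraints.tsv"
        planted_restraints.write_tsv(path)
        back = RestraintSet.read_tsv(path)
        assert back.active_receptor == planted_restraints.active_receptor
        assert back.active_ligand == planted_restraints.active_ligand
        assert back.d_c == planted_restraints.d_c

    def test_unknown_restraint_residues_rejected(self, planted_complex):
        receptor, ligand, _ = planted_complex
        rs = RestraintSet(frozenset({999}), frozenset({1}), 8.0)
        with pytest.raises(ValueError, match="999"):
            restraint_satisfaction(receptor, ligand, IDENTITY(), rs)


class TestPoseGeneration:
    def test_default_pose_count_is_ten(self, planted_complex,
                                       planted_restraints):
        receptor, ligand, _ = planted_complex
        poses = generate_poses(receptor, ligand, planted_restraints, seed=5)
        assert len(poses) == 10
        assert [p.index for p in poses] == list(range(1, 11))

    def test_same_seed_identical_transforms(self, planted_complex,
                                            planted_restraints):
        receptor, ligand, _ = planted_complex
        a = generate_poses(receptor, ligand, planted_restraints, seed=5)
        b = generate_poses(receptor, ligand, planted_restraints, seed=5)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.rotation, pb.rotation)
            assert np.array_equal(pa.translation, pb.translation)

    def test_all_poses_satisfy_half_of_restraints(self, planted_complex,
                                                  planted_restraints):
        receptor, ligand, _ = planted_complex
        poses = generate_poses(receptor, ligand, planted_restraints, seed=5)
        for pose in poses:
            frac, _ = restraint_satisfaction(receptor, ligand, pose,
                                             planted_restraints)
            assert frac >= 0.5

    def test_poses_land_at_contact_distance(self, planted_complex,
                                            planted_restraints):
        receptor, ligand, _ = planted_complex
        rec_all = np.vstack([receptor.backbone, receptor.sidechain])
        for pose in generate_poses(receptor, ligand, planted_restraints,
                                   n=3, seed=5):
            lig_all = np.vstack([pose.apply(ligand.backbone),
                                 pose.apply(ligand.sidechain)])
            assert cdist(rec_all, lig_all).min() == pytest.approx(4.0, abs=0.05)

    def test_rotation_validity(self, planted_complex, planted_restraints):
        receptor, ligand, _ = planted_complex
        for pose in generate_poses(receptor, ligand, planted_restraints,
                                   n=3, seed=5):
            R = pose.rotation
            assert np.abs(R @ R.T - np.eye(3)).max() < 1e-9
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(ValueError, match="orthogonal"):
            Pose(index=1, rotation=np.eye(3) * 1.01, translation=np.zeros(3))


class TestScoring:
    def test_far_apart_only_restraint_term(self, planted_complex,
                                           planted_restraints):
        receptor, ligand, _ = planted_complex
        far = Pose(index=1, rotation=np.eye(3),
                   translation=np.array([200.0, 0.0, 0.0])
                   + receptor.backbone.mean(axis=0))
        report = score_pose(receptor, ligand, far, planted_restraints)
        assert report.electrostatic == 0.0
        assert report.contact == 0.0
        assert report.clash == 0.0
        assert report.restraint == pytest.approx(5.0)  # w_r·(1−0)²
        assert report.total == pytest.approx(report.restraint)

    def test_unit_charge_pair_at_calibration_distance(self):
        receptor, ligand = two_residue_system(distance=5.0)
        report = score_pose(receptor, ligand, IDENTITY())
        assert report.electrostatic == pytest.approx(-1.0, rel=1e-12)

    def test_oracle_equivalence_on_planted_complex(self, planted_complex,
                                                   planted_restraints):
        receptor, ligand, truth = planted_complex
        report = score_pose(receptor, ligand, truth.planted_pose,
                            planted_restraints)
        total, elec, contact, clash, restraint, per = naive_score(
            receptor, ligand, truth.planted_pose, planted_restraints)
        assert report.total == pytest.approx(total, abs=1e-9)
        assert report.electrostatic == pytest.approx(elec, abs=1e-9)
        assert report.contact == pytest.approx(contact, abs=1e-9)
        assert report.clash == pytest.approx(clash, abs=1e-9)
        for key, value in per.items():
            assert report.per_residue[key] == pytest.approx(value, abs=1e-9)

    def test_frame_invariance(self, planted_complex, planted_restraints):
        """A global rigid transform of receptor, ligand and pose changes
        no energy term beyond 1e-9."""
        receptor, ligand, truth = planted_complex
        before = score_pose(receptor, ligand, truth.planted_pose,
                            planted_restraints)
        rng = np.random.default_rng(77)
        G = random_rotation(rng)
        g = rng.uniform(-30, 30, size=3)
        rec_t = receptor.transformed(G, g)
        lig_t = ligand.transformed(G, g)
        pose_t = truth.planted_pose.conjugated(G, g)
        after = score_pose(rec_t, lig_t, pose_t, planted_restraints)
        assert after.total == pytest.approx(before.total, abs=1e-9)
        assert after.electrostatic == pytest.approx(before.electrostatic, abs=1e-9)
        assert after.contact == pytest.approx(before.contact, abs=1e-9)
        assert after.clash == pytest.approx(before.clash, abs=1e-9)
        assert after.restraint == pytest.approx(before.restraint, abs=1e-9)

    def test_negative_clash_report_rejected(self):
        with pytest.raises(ValueError):
            EnergyReport(total=0, electrostatic=0, contact=0, clash=-1,
                         restraint=0, per_residue={},
                         restraint_fraction_satisfied=None, pose_index=1)


class TestDecomposition:
    def test_single_pair_half_split(self):
        receptor, ligand = two_residue_system(distance=5.0)
        report = score_pose(receptor, ligand, IDENTITY())
        table = decompose_energy(report)
        expected_half = report.interaction / 2
        assert table["energy"].tolist() == pytest.approx(
            [expected_half, expected_half])

    def test_out_of_range_residue_contributes_zero(self, planted_complex,
                                                   planted_restraints):
        receptor, ligand, truth = planted_complex
        report = score_pose(receptor, ligand, truth.planted_pose,
                            planted_restraints)
        lig_sc = truth.planted_pose.apply(ligand.sidechain)
        d = cdist(receptor.sidechain, lig_sc)
        weights = EnergyWeights()
        for i, num in enumerate(receptor.numbers):
            if d[i, :].min() > weights.r_cut:
                assert report.per_residue[("A", num)] == 0.0

    def test_conservation_on_scored_poses(self, planted_complex,
                                          planted_restraints):
        receptor, ligand, _ = planted_complex
        for pose in random_poses(receptor, ligand, 5, seed=21):
            report = score_pose(receptor, ligand, pose, planted_restraints)
            table = decompose_energy(report)
            assert table["energy"].sum() == pytest.approx(report.interaction,
                                                          abs=1e-9)


class TestMinimization:
    def test_score_never_increases(self, planted_complex, planted_restraints):
        receptor, ligand, _ = planted_complex
        for pose in random_poses(receptor, ligand, 3, seed=9):
            before = score_pose(receptor, ligand, pose,
                                planted_restraints).total
            after_pose = minimize_pose(receptor, ligand, pose,
                                       planted_restraints)
            after = score_pose(receptor, ligand, after_pose,
                               planted_restraints).total
            assert after <= before + 1e-12

    def test_local_minimum_returned_unchanged(self, planted_complex,
                                              planted_restraints):
        receptor, ligand, truth = planted_complex
        once = minimize_pose(receptor, ligand, truth.planted_pose,
                             planted_restraints)
        twice = minimize_pose(receptor, ligand, once, planted_restraints)
        s1 = score_pose(receptor, ligand, once, planted_restraints).total
        s2 = score_pose(receptor, ligand, twice, planted_restraints).total
        assert s2 == pytest.approx(s1, abs=1e-9)

    def test_perturbed_truth_recovers(self, planted_complex,
                                      planted_restraints):
        """From the planted pose perturbed by 3° / 1 Å, minimization lowers
        the score and does not move further from the truth interface."""
        receptor, ligand, truth = planted_complex
        pt = truth.planted_pose
        center = pt.apply(ligand.backbone).mean(axis=0)
        R = rotation_about_axis([0, 0, 1], math.radians(3.0))
        perturbed = pt.compose_after(R, center - R @ center)
        perturbed = Pose(index=perturbed.index, rotation=perturbed.rotation,
                         translation=perturbed.translation
                         + np.array([0.6, 0.6, 0.5]))
        s_pert = score_pose(receptor, ligand, perturbed,
                            planted_restraints).total
        minimized = minimize_pose(receptor, ligand, perturbed,
                                  planted_restraints)
        s_min = score_pose(receptor, ligand, minimized,
                           planted_restraints).total
        assert s_min <= s_pert
        rmsd_pert = interface_rmsd(ligand, perturbed, pt,
                                   truth.ligand_interface)
        rmsd_min = interface_rmsd(ligand, minimized, pt,
                                  truth.ligand_interface)
        assert rmsd_min <= rmsd_pert


class TestRanking:
    def report_with_total(self, idx, total):
        return (Pose(index=idx, rotation=np.eye(3), translation=np.zeros(3)),
                EnergyReport(total=total, electrostatic=total, contact=0.0,
                             clash=0.0, restraint=0.0, per_residue={},
                             restraint_fraction_satisfied=None,
                             pose_index=idx))

    def test_sort_ascending(self):
        reports = [self.report_with_total(1, -3.0),
                   self.report_with_total(2, -7.0),
                   self.report_with_total(3, -5.0)]
        ranked = rank_complexes(reports)
        assert [p.index for p, _ in ranked] == [2, 3, 1]

    def test_tie_breaks_by_lower_index(self):
        reports = [self.report_with_total(4, -5.0),
                   self.report_with_total(2, -5.0)]
        ranked = rank_complexes(reports)
        assert [p.index for p, _ in ranked] == [2, 4]

    def test_truth_proximal_pose_enriched(self, planted_complex,
                                          planted_restraints):
        """Among 50 random poses plus the planted pose, a pose within 4 Å
        interface RMSD of the truth ranks in the top 3."""
        receptor, ligand, truth = planted_complex
        pool = random_poses(receptor, ligand, 50, seed=11)
        pool.append(Pose(index=51, rotation=truth.planted_pose.rotation,
                         translation=truth.planted_pose.translation))
        ranked = rank_complexes([
            (p, score_pose(receptor, ligand, p, planted_restraints))
            for p in pool])
        top3_rmsd = [interface_rmsd(ligand, p, truth.planted_pose,
                                    truth.ligand_interface)
                     for p, _ in ranked[:3]]
        assert min(top3_rmsd) < 4.0

    def test_restraint_consistent_poses_score_better_than_random(
            self, planted_complex, planted_restraints):
        receptor, ligand, _ = planted_complex
        guided = generate_poses(receptor, ligand, planted_restraints,
                                n=10, seed=31)
        random_pool = random_poses(receptor, ligand, 100, seed=32)
        mean_guided = np.mean([
            score_pose(receptor, ligand, p, planted_restraints).total
            for p in guided])
        mean_random = np.mean([
            score_pose(receptor, ligand, p, planted_restraints).total
            for p in random_pool])
        assert mean_guided < mean_random


class TestMutationScan:
    def test_charge_mutation_signs_at_contact(self):
        """Facing a +1 partner in range: neutral→negative strengthens
        (ΔΔG < 0), neutral→positive weakens (ΔΔG > 0)."""
        receptor, ligand = two_residue_system(distance=6.0, rec_aa="K",
                                              lig_aa="N")
        scan = mutate_and_score(receptor, ligand, IDENTITY(),
                                [("B", 1, "E"), ("B", 1, "K")])
        ddg_e = scan.entries[0]["ddG"]
        ddg_k = scan.entries[1]["ddG"]
        assert ddg_e < 0 < ddg_k

    def test_contact_free_mutation_exactly_zero(self, planted_complex):
        receptor, ligand, truth = planted_complex
        lig_sc = truth.planted_pose.apply(ligand.sidechain)
        d = cdist(receptor.sidechain, lig_sc)
        far = [num for j, num in enumerate(ligand.numbers)
               if d[:, j].min() > 2 * 8.0]
        if not far:
            pytest.skip("all ligand residues within 2·d_c of the receptor")
        scan = mutate_and_score(receptor, ligand, truth.planted_pose,
                                [("B", far[0], "K")])
        assert scan.entries[0]["ddG"] == 0.0

    def test_unknown_residue_and_type_errors(self, planted_complex):
        receptor, ligand, truth = planted_complex
        with pytest.raises(KeyError, match="999"):
            mutate_and_score(receptor, ligand, truth.planted_pose,
                             [("B", 999, "K")])
        with pytest.raises(ValueError, match="residue type"):
            mutate_and_score(receptor, ligand, truth.planted_pose,
                             [("B", 1, "X")])
        with pytest.raises(ValueError, match="chain"):
            mutate_and_score(receptor, ligand, truth.planted_pose,
                             [("C", 1, "K")])

    def test_scan_records_wildtype_and_mutant_totals(self, planted_complex,
                                                     planted_restraints):
        receptor, ligand, truth = planted_complex
        target = sorted(truth.ligand_interface)[0]
        scan = mutate_and_score(receptor, ligand, truth.planted_pose,
                                [("B", target, "A")], planted_restraints)
        entry = scan.entries[0]
        assert entry["from"] in "DE"
        assert entry["ddG"] == pytest.approx(
            entry["dG_mut"] - scan.wildtype_total)
        # removing a planted salt-bridge partner must weaken the interface
        assert entry["ddG"] > 0


class TestStructureIO:
    def test_pdb_round_trip_preserves_centroids_and_charges(
            self, tmp_path, planted_complex):
        receptor, _, _ = planted_complex
        path = tmp_path / "receptor.pdb"
        receptor.to_pdb(path)
        back = Structure.from_pdb(path, "A")
        assert back.numbers == receptor.numbers
        assert np.allclose(back.backbone, receptor.backbone, atol=1e-3)
        assert np.allclose(back.sidechain, receptor.sidechain, atol=1e-3)
        assert np.array_equal(back.charges, receptor.charges)

    def test_disconnected_chain_rejected(self):
        residues = [Residue.make(1, "A", (0, 0, 0), (1, 0, 0)),
                    Residue.make(2, "A", (50, 0, 0), (51, 0, 0))]
        with pytest.raises(ValueError, match="10"):
            Structure("A", residues)

    def test_duplicate_residue_numbers_rejected(self):
        residues = [Residue.make(1, "A", (0, 0, 0), (1, 0, 0)),
                    Residue.make(1, "G", (3, 0, 0), (4, 0, 0))]
        with pytest.raises(ValueError, match="duplicate"):
            Structure("A", residues)
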