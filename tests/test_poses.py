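"""Pose geometry: polar-contact filtering and symmetry-corrected RMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dockpharm.poses import (
    IncompatiblePoseError,
    Pose,
    SiteDefinition,
    SiteProbe,
    naive_rmsd,
    polar_contact_filter,
    symmetry_rmsd,
)
from dockpharm.synth import gen_pose_pair

from helpers import brute_force_symmetry_rmsd


def make_pose(elements, coords, **kw):
    return Pose(ligand_id="lig", elements=tuple(elements), coords=np.asarray(coords, float), **kw)


def probe(x, y, z, residue="S383", atom="OG"):
    return SiteProbe(residue=residue, atom=atom, position=(x, y, z))


class TestPolarContactFilter:
    def test_distance_and_pass(self):
        pose = make_pose(["C", "O"], [[5, 5, 5], [0, 0, 0]])
        site = SiteDefinition(probes=(probe(0, 0, 2.8),))
        report = polar_contact_filter(pose, site)
        assert report.distances["S383:OG"] == pytest.approx(2.8)
        assert report.closest_atoms["S383:OG"] == 1
        assert report.passed

    def test_cutoff_boundary_inclusive_then_fail_beyond(self):
        pose = make_pose(["O"], [[0, 0, 0]])
        at_cutoff = SiteDefinition(probes=(probe(0, 0, 3.5),))
        beyond = SiteDefinition(probes=(probe(0, 0, 3.6),))
        assert polar_contact_filter(pose, at_cutoff).passed
        assert not polar_contact_filter(pose, beyond).passed

    def test_apolar_pose_fails_with_reason(self):
        pose = make_pose(["C", "C"], [[0, 0, 0], [1, 0, 0]])
        report = polar_contact_filter(pose, SiteDefinition(probes=(probe(0, 0, 1),)))
        assert not report.passed
        assert report.reason == "no polar atoms"

    def test_require_all_versus_any(self):
        pose = make_pose(["N"], [[0, 0, 0]])
        site = SiteDefinition(probes=(probe(0, 0, 2.0), probe(0, 0, 9.0, residue="H178", atom="NE2")))
        assert polar_contact_filter(pose, site, require="any").passed
        assert not polar_contact_filter(pose, site, require="all").passed

    def test_explicit_polar_flags_override_elements(self):
        pose = make_pose(["C", "O"], [[0, 0, 1], [9, 9, 9]], polar_flags=(True, False))
        report = polar_contact_filter(pose, SiteDefinition(probes=(probe(0, 0, 0),)))
        assert report.passed
        assert report.closest_atoms["S383:OG"] == 0

    def test_duplicate_probes_rejected(self):
        with pytest.raises(ValueError):
            SiteDefinition(probes=(probe(0, 0, 0), probe(1, 1, 1)))


class TestSymmetryRmsd:
    def test_identical_poses_zero(self):
        pose = make_pose(["C", "O", "O"], [[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        assert symmetry_rmsd(pose, pose) == 0.0

    def test_swapped_equivalent_atoms_zero_but_naive_positive(self):
        a = make_pose(["C", "O", "O"], [[0, 0, 0], [2, 0, 0], [0, 2, 0]])
        b = make_pose(["C", "O", "O"], [[0, 0, 0], [0, 2, 0], [2, 0, 0]])
        assert symmetry_rmsd(a, b) == pytest.approx(0.0, abs=1e-12)
        assert naive_rmsd(a, b) > 1.0

    def test_element_mismatch_reports_difference(self):
        a = make_pose(["C", "O"], [[0, 0, 0], [1, 0, 0]])
        b = make_pose(["C", "N"], [[0, 0, 0], [1, 0, 0]])
        with pytest.raises(IncompatiblePoseError, match="N"):
            symmetry_rmsd(a, b)

    @pytest.mark.parametrize("seed", range(100))
    def test_equals_brute_force_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        elements = rng.choice(["C", "O", "N"], size=6)
        ca = rng.normal(size=(6, 3)) * 3
        cb = rng.normal(size=(6, 3)) * 3
        a, b = make_pose(elements, ca), make_pose(elements, cb)
        oracle = brute_force_symmetry_rmsd(elements, ca, elements, cb)
        assert symmetry_rmsd(a, b) == pytest.approx(oracle, abs=1e-9)

    def test_symmetric_and_rigid_motion_invariant(self):
        rng = np.random.default_rng(3)
        elements = ["C", "C", "O", "N", "O", "C"]
        ca, cb = rng.normal(size=(6, 3)) * 4, rng.normal(size=(6, 3)) * 4
        a, b = make_pose(elements, ca), make_pose(elements, cb)
        assert symmetry_rmsd(a, b) == pytest.approx(symmetry_rmsd(b, a), abs=1e-12)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        shift = np.array([5.0, -2.0, 1.5])
        a2 = make_pose(elements, ca @ rot.T + shift)
        b2 = make_pose(elements, cb @ rot.T + shift)
        assert symmetry_rmsd(a2, b2) == pytest.approx(symmetry_rmsd(a, b), abs=1e-9)

    def test_invariant_under_atom_reordering(self):
        rng = np.random.default_rng(4)
        elements = np.array(["C", "O", "O", "N", "C", "C"])
        ca, cb = rng.normal(size=(6, 3)) * 4, rng.normal(size=(6, 3)) * 4
        base = symmetry_rmsd(make_pose(elements, ca), make_pose(elements, cb))
        perm = rng.permutation(6)
        shuffled = symmetry_rmsd(
            make_pose(elements[perm], ca[perm]), make_pose(elements, cb)
        )
        assert shuffled == pytest.approx(base, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_never_exceeds_naive(self, seed):
        rng = np.random.default_rng(seed)
        elements = ["C", "O", "C", "O", "N", "C"]
        a = make_pose(elements, rng.normal(size=(6, 3)) * 3)
        b = make_pose(elements, rng.normal(size=(6, 3)) * 3)
        assert symmetry_rmsd(a, b) <= naive_rmsd(a, b) + 1e-12


class TestNaiveRmsd:
    def test_uniform_translation(self):
        coords = np.random.default_rng(0).normal(size=(5, 3))
        a = make_pose(["C"] * 5, coords)
        b = make_pose(["C"] * 5, coords + [1.0, 0.0, 0.0])
        assert naive_rmsd(a, b) == pytest.approx(1.0)
        assert symmetry_rmsd(a, b) <= 1.0 + 1e-12

    def test_count_mismatch_rejected(self):
        a = make_pose(["C"], [[0, 0, 0]])
        b = make_pose(["C", "C"], [[0, 0, 0], [1, 1, 1]])
        with pytest.raises(IncompatiblePoseError):
            naive_rmsd(a, b)


class TestGeneratedPairs:
    def test_zero_target_gives_zero_rmsd_despite_permutation(self):
        a, b, true_rmsd = gen_pose_pair(6, ["O", "C"], 0.0, seed=5)
        assert true_rmsd == 0.0
        assert symmetry_rmsd(a, b) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_construction_matches_brute_force(self, seed):
        a, b, true_rmsd = gen_pose_pair(6, ["O"], 1.2, seed=seed)
        oracle = brute_force_symmetry_rmsd(a.elements, a.coords, b.elements, b.coords)
        assert oracle == pytest.approx(true_rmsd, abs=1e-6)
        assert true_rmsd == pytest.approx(1.2, abs=1e-6)

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError):
            gen_pose_pair(6, ["O"], -1.0, seed=1)


class TestAlignmentOption:
    def test_align_recovers_zero_after_rigid_motion_of_one_pose(self):
        rng = np.random.default_rng(6)
        elements = ["C", "O", "O", "N", "C", "C"]
        coords = rng.normal(size=(6, 3)) * 4
        a = make_pose(elements, coords)
        rot = Rotation.from_euler("xyz", [0.5, 1.0, -0.7]).as_matrix()
        b = make_pose(elements, coords @ rot.T + np.array([3.0, -1.0, 2.0]))
        assert symmetry_rmsd(a, b) > 1.0           # frames differ
        assert symmetry_rmsd(a, b, align=True) == pytest.approx(0.0, abs=1e-9)

    def test_align_reduces_rigidly_moved_noisy_copy_to_noise_level(self):
        rng = np.random.default_rng(7)
        elements = ["C", "O", "N", "C", "C", "O"]
        coords = rng.normal(size=(6, 3)) * 4
        noisy = coords + rng.normal(scale=0.05, size=(6, 3))
        rot = Rotation.from_euler("xyz", [1.2, 0.4, -0.9]).as_matrix()
        a = make_pose(elements, coords)
        b = make_pose(elements, noisy @ rot.T + np.array([10.0, 0.0, 0.0]))
        assert symmetry_rmsd(a, b) > 1.0
        assert symmetry_rmsd(a, b, align=True) < 0.2
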