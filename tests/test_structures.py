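import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deerdock.structures import (
    C2Pose,
    RigidTransform,
    Structure,
    buried_surface,
    clash_and_contact,
    make_c2_dimer,
    read_pdb,
    rotation_y,
    rotation_z,
    write_pdb,
)
from deerdock.synthetic_data import ToySpec, make_toy_protomer

from conftest import single_atom_structure

PDB_3ATOMS = """\
ATOM      1  N   ALA A   1      11.000  22.000  33.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      12.500  22.000  33.000  1.00  0.00           C
ATOM      3  C   ALA A   1      13.000  23.500  33.000  1.00  0.00           C
END
"""


class TestReadPdb:
    def test_three_atoms_angstrom_to_nm(self, tmp_path):
        path = tmp_path / "three.pdb"
        path.write_text(PDB_3ATOMS)
        s = read_pdb(path)
        assert len(s) == 3
        np.testing.assert_allclose(s.coords[0], [1.1, 2.2, 3.3], atol=1e-6)
        np.testing.assert_allclose(s.coords[1], [1.25, 2.2, 3.3], atol=1e-6)
        assert list(s.atom_names) == ["N", "CA", "C"]

    def test_duplicate_atom_key_raises(self, tmp_path):
        dup = PDB_3ATOMS.replace("  C   ALA A   1      13.000", "  N   ALA A   1      13.000")
        path = tmp_path / "dup.pdb"
        path.write_text(dup)
        with pytest.raises(ValueError, match="duplicate"):
            read_pdb(path)

    def test_unparseable_record_names_line(self, tmp_path):
        bad = PDB_3ATOMS.replace("12.500", "twelve")
        path = tmp_path / "bad.pdb"
        path.write_text(bad)
        with pytest.raises(ValueError, match="line 2"):
            read_pdb(path)

    def test_hydrogens_and_waters_skipped(self, tmp_path):
        text = PDB_3ATOMS.replace(
            "END",
            "ATOM      4  H   ALA A   1      11.000  22.000  34.000  1.00  0.00           H\n"
            "HETATM    5  O   HOH A  99      15.000  22.000  33.000  1.00  0.00           O\n"
            "END",
        )
        path = tmp_path / "mixed.pdb"
        path.write_text(text)
        assert len(read_pdb(path)) == 3

    def test_empty_selection_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(ValueError, match="no protein heavy atoms"):
            read_pdb(path)

    def test_round_trip(self, tmp_path):
        protomer = make_toy_protomer(ToySpec(seed=4))
        p1 = tmp_path / "a.pdb"
        p2 = tmp_path / "b.pdb"
        write_pdb(protomer, p1)
        s1 = read_pdb(p1)
        write_pdb(s1, p2)
        s2 = read_pdb(p2)
        # PDB stores 3 decimals in Angstrom -> 1e-4 nm
        np.testing.assert_allclose(s1.coords, s2.coords, atol=1e-4)
        np.testing.assert_allclose(s1.coords, protomer.coords, atol=1e-4)


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        with pytest.raises(ValueError, match="determinant"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_composition_associative(self):
        rng = np.random.default_rng(0)

        def random_tf(seed):
            r = np.random.default_rng(seed)
            q, _ = np.linalg.qr(r.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] = -q[:, 0]
            return RigidTransform(q, r.normal(size=3))

        a, b, c = (random_tf(s) for s in (1, 2, 3))
        pts = rng.normal(size=(5, 3))
        left = a.compose(b).compose(c).apply(pts)
        right = a.compose(b.compose(c)).apply(pts)
        np.testing.assert_allclose(left, right, atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(
        alpha=st.floats(0, 360),
        beta=st.floats(0, 180),
        seed=st.integers(0, 10_000),
    )
    def test_preserves_pairwise_distances(self, alpha, beta, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 3))
        tf = RigidTransform(rotation_y(beta) @ rotation_z(alpha), rng.normal(size=3))
        moved = tf.apply(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestMakeC2Dimer:
    def test_identity_pose_gives_z_flip(self, toy_protomer):
        a, b = make_c2_dimer(toy_protomer, C2Pose(0, 0, 0, 0))
        centered = toy_protomer.coords - toy_protomer.geometric_center
        np.testing.assert_allclose(a.coords, centered, atol=1e-12)
        np.testing.assert_allclose(b.coords, centered @ rotation_z(180).T, atol=1e-12)

    def test_c2_closure(self, toy_protomer):
        a, b = make_c2_dimer(toy_protomer, C2Pose(33.0, 40.0, 1.2, -0.7))
        rz = rotation_z(180)
        np.testing.assert_allclose(a.coords @ rz.T, b.coords, atol=1e-9)
        np.testing.assert_allclose(b.coords @ rz.T, a.coords, atol=1e-9)

    def test_hand_computed_placement(self):
        # atom at (1,0,0) in an origin-centred structure: rot_z(90) then
        # translate(3,0) puts it at (3,1,0); the C2 partner lands at (-3,-1,0)
        s = Structure(
            chain_ids=np.array(["A", "A"]),
            res_ids=np.array([1, 2]),
            res_names=np.array(["ALA", "ALA"]),
            atom_names=np.array(["CA", "CA"]),
            elements=np.array(["C", "C"]),
            coords=np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]]),
        )
        a, b = make_c2_dimer(s, C2Pose(90.0, 0.0, 3.0, 0.0))
        np.testing.assert_allclose(a.coords[0], [3.0, 1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(b.coords[0], [-3.0, -1.0, 0.0], atol=1e-12)

    def test_gauge_global_rotation_compensated_by_alpha(self, toy_protomer):
        from dataclasses import replace

        delta = 25.0
        pose = C2Pose(80.0, 15.0, 2.0, 1.0)
        a1, _ = make_c2_dimer(toy_protomer, pose)
        rotated = replace(toy_protomer, coords=toy_protomer.coords @ rotation_z(delta).T)
        a2, _ = make_c2_dimer(rotated, C2Pose(pose.alpha - delta, pose.beta, pose.x, pose.y))
        np.testing.assert_allclose(a1.coords, a2.coords, atol=1e-9)

    def test_empty_protomer_rejected(self):
        s = single_atom_structure([0, 0, 0])
        import dataclasses

        empty = Structure(
            np.array([], dtype=str),
            np.array([], dtype=int),
            np.array([], dtype=str),
            np.array([], dtype=str),
            np.array([], dtype=str),
            np.zeros((0, 3)),
        )
        with pytest.raises(ValueError, match="non-empty"):
            make_c2_dimer(empty, C2Pose(0, 0, 0, 0))


class TestClashContact:
    def test_self_overlap_clashes(self, toy_protomer):
        clash, contact, dmin = clash_and_contact(toy_protomer, toy_protomer)
        assert clash and contact and dmin == 0.0

    def test_far_apart(self, toy_protomer):
        from dataclasses import replace

        far = replace(toy_protomer, coords=toy_protomer.coords + np.array([50.0, 0, 0]))
        clash, contact, dmin = clash_and_contact(toy_protomer, far)
        assert not clash and not contact
        # within the protomer's own extent of the 50 nm shift
        assert dmin == pytest.approx(50.0, abs=6.0)

    def test_single_ca_at_point_seven(self):
        a = single_atom_structure([0, 0, 0])
        b = single_atom_structure([0.7, 0, 0])
        clash, contact, dmin = clash_and_contact(a, b)
        assert (clash, contact) == (False, True)
        assert dmin == pytest.approx(0.7)

    def test_no_ca_raises(self):
        a = single_atom_structure([0, 0, 0], name="CB")
        with pytest.raises(ValueError, match="no CA"):
            clash_and_contact(a, a)

    def test_cut_ordering_enforced(self, toy_protomer):
        with pytest.raises(ValueError, match="clash_cut"):
            clash_and_contact(toy_protomer, toy_protomer, clash_cut=2.0, contact_cut=1.0)


class TestBuriedSurface:
    def test_separated_protomers_bury_nothing(self, toy_protomer):
        from dataclasses import replace

        far = replace(toy_protomer, coords=toy_protomer.coords + np.array([50.0, 0, 0]))
        area = buried_surface(toy_protomer, far, n_points=240)
        assert abs(area) < 1.0

    def test_two_sphere_analytic_overlap(self):
        # two radius-0.2 nm spheres, centres 0.3 nm apart, probe 0:
        # buried area = 2 caps = 4 pi R h with h = R - d/2
        a = single_atom_structure([0.0, 0, 0], element="X")
        b = single_atom_structure([0.3, 0, 0], element="X")
        area = buried_surface(a, b, probe=0.0, n_points=2000, radii={"X": 0.2})
        analytic = 4.0 * np.pi * 0.2 * 0.05 * 100.0
        assert area == pytest.approx(analytic, rel=0.02)

    def test_symmetric_under_argument_swap(self, toy_protomer):
        a, b = make_c2_dimer(toy_protomer, C2Pose(0.0, 0.0, 2.2, 0.0))
        assert buried_surface(a, b, n_points=240) == pytest.approx(
            buried_surface(b, a, n_points=240), abs=1e-9
        )

    def test_unknown_element_raises(self):
        a = single_atom_structure([0, 0, 0], element="QQ")
        with pytest.raises(ValueError, match="QQ"):
            buried_surface(a, a, n_points=240)

    def test_convergence_with_point_doubling(self, toy_protomer):
        a, b = make_c2_dimer(toy_protomer, C2Pose(0.0, 0.0, 2.2, 0.0))
        coarse = buried_surface(a, b, n_points=960)
        fine = buried_surface(a, b, n_points=1920)
        assert abs(fine - coarse) <= 0.01 * max(abs(fine), 1.0)

    def test_too_few_points_rejected(self, toy_protomer):
        with pytest.raises(ValueError, match="n_points"):
            buried_surface(toy_protomer, toy_protomer, n_points=50)
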