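"""Geometric primitives: PDB I/O, superposition, RMSD, COM, SASA."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from pepevolve.geometry import (
    Atom,
    PDBParseError,
    ResidueSelection,
    Structure,
    center_of_mass,
    coords_rmsd,
    kabsch_superpose,
    read_pdb,
    rmsd,
    shrake_rupley_sasa,
    sphere_points,
    write_pdb,
)
from pepevolve.synthetic import chain_structure


def single_atom(element="C", position=(0.0, 0.0, 0.0), name=None):
    return Atom(
        name=name or element,
        element=element,
        residue_number=1,
        residue_name="ALA",
        chain_id="A",
        position=np.array(position, dtype=float),
    )


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

class TestReadPDB:
    def test_hand_written_glycine(self, tiny_gly_pdb):
        models = read_pdb(tiny_gly_pdb)
        assert len(models) == 1
        structure = models[0]
        assert len(structure) == 3
        assert structure.residue_ids() == [("A", 1, "")]
        np.testing.assert_allclose(
            structure.coordinates,
            [[0, 0, 0], [1.5, 0, 0], [2.4, 1.1, 0]],
        )
        assert [a.element for a in structure.atoms] == ["N", "C", "C"]

    def test_multi_model_duplicates(self, tmp_path):
        body = (
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
        )
        path = tmp_path / "two.pdb"
        path.write_text(f"MODEL        1\n{body}ENDMDL\nMODEL        2\n{body}ENDMDL\n")
        models = read_pdb(path)
        assert len(models) == 2
        np.testing.assert_array_equal(models[0].coordinates, models[1].coordinates)
        assert [m.model_id for m in models] == [1, 2]

    def test_malformed_atom_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       1.000   xxxxx   3.000  1.00  0.00           C\n"
        )
        with pytest.raises(PDBParseError, match="line 2"):
            read_pdb(path)

    def test_empty_model_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("MODEL        1\nENDMDL\n")
        with pytest.raises(PDBParseError):
            read_pdb(path)

    def test_no_atom_records_rejected(self, tmp_path):
        path = tmp_path / "none.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(PDBParseError):
            read_pdb(path)

    def test_hetatm_excluded_by_default(self, tmp_path):
        path = tmp_path / "het.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O\n"
        )
        assert len(read_pdb(path)[0]) == 1
        assert len(read_pdb(path, include_hetatm=True)[0]) == 2

    def test_insertion_code_preserved(self, tmp_path):
        path = tmp_path / "icode.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A  52A      0.000   0.000   0.000  1.00  0.00           C\n"
        )
        atom = read_pdb(path)[0].atoms[0]
        assert atom.residue_id == ("A", 52, "A")

    def test_cross_parser_oracle(self, tmp_path):
        """Atom/residue counts and coordinates agree with an independent
        reference parser (Bio.PDB) on the same file."""
        Bio_PDB = pytest.importorskip("Bio.PDB")
        structure = chain_structure("GASDEVRLYTW", chain_id="A")
        path = tmp_path / "chain.pdb"
        write_pdb(structure, path)

        ours = read_pdb(path)[0]
        parser = Bio_PDB.PDBParser(QUIET=True)
        ref = parser.get_structure("x", str(path))
        ref_atoms = list(ref.get_atoms())
        assert len(ours) == len(ref_atoms)
        assert len(ours.residue_ids()) == len(list(ref.get_residues()))
        np.testing.assert_allclose(
            ours.coordinates,
            np.array([a.get_coord() for a in ref_atoms]),
            atol=1e-3,
        )

    def test_write_read_round_trip_multi_model(self, tmp_path):
        m1 = chain_structure("ACD", chain_id="A")
        m2 = Structure(
            [
                Atom(a.name, a.element, a.residue_number, a.residue_name,
                     a.chain_id, a.position + 1.0)
                for a in m1.atoms
            ],
            model_id=2,
        )
        path = tmp_path / "rt.pdb"
        write_pdb([m1, m2], path)
        models = read_pdb(path)
        assert len(models) == 2
        np.testing.assert_allclose(models[0].coordinates, m1.coordinates, atol=1e-3)
        np.testing.assert_allclose(models[1].coordinates, m2.coordinates, atol=1e-3)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

class TestKabsch:
    def test_identical_sets(self, rng):
        pts = rng.normal(size=(6, 3))
        rotation, translation, value = kabsch_superpose(pts, pts)
        assert value == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(translation, 0.0, atol=1e-10)

    def test_isometry_recovered(self, rng):
        pts = rng.normal(size=(5, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([5.0, 5.0, 5.0])
        _, _, value = kabsch_superpose(pts, moved)
        assert value == pytest.approx(0.0, abs=1e-9)

    def test_rotation_always_proper(self, rng):
        # A mirrored copy tempts the SVD solution into a reflection.
        pts = rng.normal(size=(5, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        rotation, _, _ = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_grid_search(self, rng):
        """Minimum RMSD agrees with brute-force minimization over rotations
        sampled densely from the quaternion sphere."""
        a = rng.normal(size=(4, 3))
        b = a + rng.normal(scale=0.3, size=(4, 3))
        _, _, value = kabsch_superpose(a, b)

        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        quats = np.random.default_rng(0).normal(size=(200_000, 4))
        quats /= np.linalg.norm(quats, axis=1, keepdims=True)
        best = np.inf
        for mat in Rotation.from_quat(quats).as_matrix():
            cand = np.sqrt(np.mean(np.sum((ac @ mat.T - bc) ** 2, axis=1)))
            best = min(best, cand)
        assert value == pytest.approx(best, abs=2e-3)
        assert value <= best + 1e-12  # Kabsch is the true minimum

    def test_error_cases(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_superpose(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)

    @given(st.integers(0, 10_000))
    def test_symmetry(self, seed):
        pts_rng = np.random.default_rng(seed)
        a = pts_rng.normal(size=(5, 3))
        b = pts_rng.normal(size=(5, 3))
        assert kabsch_superpose(a, b)[2] == pytest.approx(
            kabsch_superpose(b, a)[2], rel=1e-9
        )


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

class TestRmsd:
    def test_frame_vs_itself(self):
        frame = chain_structure("ACDE")
        assert rmsd(frame, frame) == pytest.approx(0.0, abs=1e-12)

    def test_translation_with_and_without_fit(self):
        frame = chain_structure("ACDE")
        shifted = Structure(
            [
                Atom(a.name, a.element, a.residue_number, a.residue_name,
                     a.chain_id, a.position + np.array([3.0, 4.0, 0.0]))
                for a in frame.atoms
            ]
        )
        assert rmsd(frame, shifted, fit=False) == pytest.approx(5.0)
        assert rmsd(frame, shifted, fit=True) == pytest.approx(0.0, abs=1e-9)

    def test_matches_hand_computation(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], float)
        b = a.copy()
        b[0] = [0.3, 0, 0]
        b[4] = [1, 1, 1.4]
        expected = math.sqrt((0.3**2 + 0.4**2) / 5)
        assert coords_rmsd(a, b, fit=False) == pytest.approx(expected)

    def test_empty_selection_rejected(self):
        frame = chain_structure("ACDE")
        with pytest.raises(ValueError):
            rmsd(frame, frame, ResidueSelection("A", (99,)))


# ---------------------------------------------------------------------------
# Center of mass
# ---------------------------------------------------------------------------

class TestCenterOfMass:
    def test_single_atom(self):
        s = Structure([single_atom(position=(1, 2, 3))])
        np.testing.assert_allclose(center_of_mass(s), [1, 2, 3])

    def test_equal_masses_symmetric(self):
        s = Structure(
            [single_atom(position=(-2, 0, 0)), single_atom(position=(2, 0, 0))]
        )
        np.testing.assert_allclose(center_of_mass(s), [0, 0, 0], atol=1e-12)

    def test_mixed_elements_hand_computed(self):
        s = Structure(
            [
                single_atom("C", (0, 0, 0)),
                single_atom("O", (1, 0, 0), name="O"),
                single_atom("N", (0, 1, 0), name="N"),
            ]
        )
        m_c, m_o, m_n = 12.011, 15.999, 14.007
        total = m_c + m_o + m_n
        expected = np.array([m_o / total, m_n / total, 0.0])
        np.testing.assert_allclose(center_of_mass(s), expected)

    def test_geometric_centroid_flag(self):
        s = Structure([single_atom("C", (0, 0, 0)), single_atom("O", (1, 0, 0), name="O")])
        np.testing.assert_allclose(center_of_mass(s, weighted=False), [0.5, 0, 0])

    def test_unknown_element_lists_atom(self):
        s = Structure([single_atom("XX", name="XX1")])
        with pytest.raises(KeyError, match="XX1"):
            center_of_mass(s)

    @given(st.integers(0, 10_000))
    def test_equivariant_under_isometry(self, seed):
        local = np.random.default_rng(seed)
        s = chain_structure("ACDE")
        rot = Rotation.random(random_state=int(seed) % (2**31)).as_matrix()
        shift = local.normal(size=3)
        moved = Structure(
            [
                Atom(a.name, a.element, a.residue_number, a.residue_name,
                     a.chain_id, rot @ a.position + shift)
                for a in s.atoms
            ]
        )
        np.testing.assert_allclose(
            center_of_mass(moved), rot @ center_of_mass(s) + shift, atol=1e-9
        )


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

class TestSasa:
    def test_single_carbon_analytic_sphere(self):
        s = Structure([single_atom("C")])
        result = shrake_rupley_sasa(s, probe_radius=1.4, n_points=960)
        analytic = 4 * math.pi * (1.7 + 1.4) ** 2
        assert result.total == pytest.approx(analytic, rel=0.01)

    def test_disjoint_atoms_additive(self):
        one = Structure([single_atom("C")])
        two = Structure(
            [single_atom("C"), single_atom("C", (100.0, 0, 0))]
        )
        r1 = shrake_rupley_sasa(one)
        r2 = shrake_rupley_sasa(two)
        assert r2.total == pytest.approx(2 * r1.total, rel=1e-9)

    def test_fully_caged_atom_buried(self):
        # Central atom surrounded by a tight octahedral + cubic cage.
        offsets = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if (dx, dy, dz) != (0, 0, 0):
                        offsets.append(np.array([dx, dy, dz], float) * 2.0)
        atoms = [single_atom("C")] + [single_atom("C", tuple(o)) for o in offsets]
        s = Structure(atoms)
        result = shrake_rupley_sasa(s)
        assert result.per_atom[0] == pytest.approx(0.0, abs=1e-9)

    def test_n_points_floor(self):
        s = Structure([single_atom("C")])
        with pytest.raises(ValueError):
            shrake_rupley_sasa(s, n_points=9)

    def test_convergence_monotone_in_n_points(self):
        s = Structure([single_atom("C")])
        analytic = 4 * math.pi * (1.7 + 1.4) ** 2
        errors = [
            abs(shrake_rupley_sasa(s, n_points=n).total - analytic)
            for n in (60, 240, 960)
        ]
        assert errors[0] >= errors[1] >= errors[2]

    def test_per_residue_sums_to_total(self):
        s = chain_structure("ACDEF")
        result = shrake_rupley_sasa(s)
        assert sum(result.per_residue.values()) == pytest.approx(result.total)

    def test_translation_invariance_exact(self):
        s = chain_structure("ACD")
        moved = Structure(
            [
                Atom(a.name, a.element, a.residue_number, a.residue_name,
                     a.chain_id, a.position + np.array([7.0, -3.0, 11.0]))
                for a in s.atoms
            ]
        )
        assert shrake_rupley_sasa(moved).total == pytest.approx(
            shrake_rupley_sasa(s).total, rel=1e-12
        )

    @given(st.integers(0, 1000))
    def test_rotation_invariance_within_lattice_error(self, seed):
        # The quadrature lattice is fixed in space, so rotating the molecule
        # re-discretizes occlusion: invariance holds to the lattice error.
        s = chain_structure("ACD")
        rot = Rotation.random(random_state=seed).as_matrix()
        moved = Structure(
            [
                Atom(a.name, a.element, a.residue_number, a.residue_name,
                     a.chain_id, rot @ a.position)
                for a in s.atoms
            ]
        )
        assert shrake_rupley_sasa(moved).total == pytest.approx(
            shrake_rupley_sasa(s).total, rel=0.02
        )

    def test_agrees_with_mdtraj(self, tmp_path):
        """Dual-route check against an independent Shrake-Rupley
        implementation on the same structure and radii conventions."""
        md = pytest.importorskip("mdtraj")
        s = chain_structure("GAV", chain_id="A")
        path = tmp_path / "chain.pdb"
        from pepevolve.geometry import write_pdb

        write_pdb(s, path)
        traj = md.load_pdb(str(path))
        ref = float(md.shrake_rupley(traj, probe_radius=0.14, n_sphere_points=960).sum()) * 100.0
        ours = shrake_rupley_sasa(s, probe_radius=1.4, n_points=960).total
        assert ours == pytest.approx(ref, rel=0.03)


def test_sphere_points_unit_norm_and_deterministic():
    pts = sphere_points(240)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    np.testing.assert_array_equal(pts, sphere_points(240))
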