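"""Structure parsing, environment retrieval, SASA and residue depth."""

import io

import numpy as np
import pytest

from memstab.structures import (
    PDBFormatError,
    ResidueNotFoundError,
    compute_atom_sasa,
    get_environment,
    read_pdb,
    residue_depth,
    solvent_accessibility,
    write_pdb,
)

from conftest import ALTLOC_PDB, TINY_PDB, TWO_MODEL_PDB, make_residue, make_structure


class TestReadPDB:
    def test_tiny_fixture_parses_to_one_chain_three_residues(self):
        s = read_pdb(TINY_PDB)
        assert list(s.chains) == ["A"]
        assert [r.aa3 for r in s.chains["A"]] == ["ALA", "GLY", "SER"]
        assert s.n_atoms() == 15

    def test_roundtrip_preserves_atoms_names_and_coords(self):
        s = read_pdb(TINY_PDB)
        s2 = read_pdb(write_pdb(s))
        assert s2.n_atoms() == s.n_atoms()
        for a, b in zip(s.atoms(), s2.atoms()):
            assert a.name == b.name
            np.testing.assert_allclose(a.coords, b.coords, atol=5e-4)

    def test_only_first_model_retained(self):
        s = read_pdb(TWO_MODEL_PDB)
        assert s.n_atoms() == 4
        # model-1 coordinates, not model-2
        np.testing.assert_allclose(next(s.atoms()).coords, [0.0, 0.0, 0.0])

    def test_altloc_resolves_to_highest_occupancy(self):
        s = read_pdb(ALTLOC_PDB)
        res = s.residue("A", 1)
        cbs = [a for a in res.atoms if a.name == "CB"]
        assert len(cbs) == 1
        np.testing.assert_allclose(cbs[0].coords, [2.0, -0.8, 1.2])  # altloc A, occ 0.60

    def test_malformed_coordinates_reported_with_line_number(self):
        bad = TINY_PDB.replace("   1.200   0.800   0.000", "   1.200   xx.800   0.000")
        with pytest.raises(PDBFormatError, match="line 3"):
            read_pdb(bad)

    def test_empty_input_rejected(self):
        with pytest.raises(PDBFormatError):
            read_pdb("REMARK nothing here\nEND\n")


class TestEnvironment:
    def test_radius_zero_is_empty(self, helix):
        assert get_environment(helix, ("A", 5), 0.0) == []

    def test_missing_residue_error_names_chain_and_number(self, helix):
        with pytest.raises(ResidueNotFoundError, match="999"):
            get_environment(helix, ("A", 999), 5.0)

    def test_oligomer_flag_controls_partner_chain(self, dimer):
        # chains are 9 Å apart; some atom pairs across the interface are < 8 Å
        key = ("A", 10)
        with_partner = get_environment(dimer, key, 8.0, oligomer=True)
        without = get_environment(dimer, key, 8.0, oligomer=False)
        partner_atoms = [a for a in with_partner if a.residue_key[0] == "B"]
        assert partner_atoms, "expected contacting atoms on chain B within 8 Å"
        assert all(a.residue_key[0] == "A" for a in without)
        own_atoms_with = [a for a in with_partner if a.residue_key[0] == "A"]
        assert {id(a) for a in own_atoms_with} == {id(a) for a in without}

    def test_matches_brute_force_scan(self, helix):
        key = ("A", 12)
        res = helix.residue("A", 12)
        got = {id(a) for a in get_environment(helix, key, 10.0)}
        expected = set()
        res_xyz = res.coords()
        for atom in helix.atoms():
            if atom.residue_key == res.key:
                continue
            d = min(np.linalg.norm(atom.coords - x) for x in res_xyz)
            if d <= 10.0:
                expected.add(id(atom))
        assert got == expected


class TestSASA:
    def test_isolated_carbon_matches_sphere_area(self):
        s = make_structure(
            [make_residue("A", 1, "ALA", "A", [("CB", "C", (0, 0, 0))])]
        )
        sasa = compute_atom_sasa(s, probe=1.4, n_points=2000)
        assert sasa[0] == pytest.approx(4 * np.pi * 3.1**2, rel=1e-6)

    def test_nonoverlapping_spheres_sum_to_isolated_areas(self):
        atoms = [("CB", "C", (20.0 * i, 0, 0)) for i in range(4)]
        s = make_structure([make_residue("A", 1, "ALA", "A", atoms)])
        sasa = compute_atom_sasa(s, probe=1.4, n_points=1000)
        np.testing.assert_allclose(sasa, 4 * np.pi * 3.1**2, rtol=1e-6)

    def test_caged_atom_is_buried(self):
        cage = _cage_structure()
        sasa = compute_atom_sasa(cage, probe=1.4, n_points=500)
        assert sasa[0] == pytest.approx(0.0, abs=1e-9)  # first atom = centre

    def test_refines_towards_high_density_estimate(self, helix):
        coarse = solvent_accessibility(helix, ("A", 3), n_points=400)[0]
        fine = solvent_accessibility(helix, ("A", 3), n_points=10_000)[0]
        assert coarse == pytest.approx(fine, rel=0.02)

    def test_agrees_with_biopython_shrake_rupley(self, helix):
        """Independent oracle: Bio.PDB's Shrake–Rupley on identical radii."""
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley
        from memstab.structures import VDW_RADII

        bio = PDBParser(QUIET=True).get_structure("h", io.StringIO(write_pdb(helix)))
        ShrakeRupley(probe_radius=1.4, n_points=960, radii_dict=dict(VDW_RADII)).compute(
            bio, level="S"
        )
        ours = compute_atom_sasa(helix, probe=1.4, n_points=960).sum()
        assert ours == pytest.approx(bio.sasa, rel=0.01)

    def test_point_count_floor(self, helix):
        with pytest.raises(ValueError, match="n_points"):
            compute_atom_sasa(helix, n_points=10)

    def test_unknown_element_warns_and_uses_default(self):
        s = make_structure(
            [make_residue("A", 1, "UNK", "X", [("FE", "FE", (0, 0, 0))])]
        )
        with pytest.warns(UserWarning, match="van der Waals"):
            sasa = compute_atom_sasa(s, probe=1.4, n_points=500)
        assert sasa[0] == pytest.approx(4 * np.pi * (1.8 + 1.4) ** 2, rel=1e-6)


class TestResidueDepth:
    def test_surface_residue_on_helix_is_shallow(self, helix):
        # a bare helix is all surface: every atom sits within a couple of Å
        # of an exposed atom
        assert residue_depth(helix, ("A", 15), n_points=200) < 2.0

    def test_caged_centre_equals_nearest_exposed_distance(self):
        cage = _cage_structure()
        depth = residue_depth(cage, ("A", 1), n_points=500)
        # the centre atom's only exposed neighbours are the cage shell at 3 Å
        assert depth == pytest.approx(3.0, abs=1e-9)

    def test_depth_nonnegative_everywhere(self, dimer):
        for chain, residues in dimer.chains.items():
            for res in residues[::5]:
                assert residue_depth(dimer, (chain, res.number), n_points=120) >= 0.0


def _cage_structure():
    """A centre atom enclosed by a dense spherical shell of carbons at 3 Å."""
    golden = np.pi * (1 + 5**0.5)
    shell = []
    n = 60
    for i in range(n):
        phi = np.arccos(1 - 2 * (i + 0.5) / n)
        theta = golden * (i + 0.5)
        shell.append(3.0 * np.array([np.cos(theta) * np.sin(phi),
                                     np.sin(theta) * np.sin(phi), np.cos(phi)]))
    centre = make_residue("A", 1, "ALA", "A", [("CB", "C", (0.0, 0.0, 0.0))])
    cage = make_residue(
        "A", 2, "ALA", "A", [(f"C{i}", "C", tuple(p)) for i, p in enumerate(shell)]
    )
    return make_structure([centre, cage])
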