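"""Structure parsing, contact interfaces and Shrake-Rupley accessibility."""

import math

import numpy as np
import pytest

from fe_s_conserv.structures import (
    Atom,
    MAX_SASA_TABLES,
    ResidueId,
    Structure,
    contact_residues,
    delta_sasa_on_binding,
    parse_structure,
    relative_sasa,
    shrake_rupley_sasa,
)
from fe_s_conserv.synth import make_toy_complex

from _oracles import brute_force_contacts

TWO_ATOM_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BGLY A   1       5.000   0.000   0.000  0.40  0.00           C
ATOM      3  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O
HETATM    4  P   PLP B   1      10.000   0.000   0.000  1.00  0.00           P
END
"""


class TestParseStructure:
    def test_minimal_two_atom_record(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(TWO_ATOM_PDB)
        s = parse_structure(p)
        assert len(s.atoms) == 2
        assert s.chains == {"A"}

    def test_altloc_water_and_hetero_policy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        s = parse_structure(p)
        # highest-occupancy altloc kept, water dropped, ligand retained+flagged
        gly = [a for a in s.atoms if a.residue_name == "GLY"]
        assert len(gly) == 1 and gly[0].coordinates[0] == pytest.approx(0.0)
        assert not any(a.residue_name == "HOH" for a in s.atoms)
        plp = [a for a in s.atoms if a.residue_name == "PLP"]
        assert len(plp) == 1 and plp[0].hetero

    def test_mmcif_round_trip(self, tmp_path):
        import gemmi

        p = tmp_path / "two.pdb"
        p.write_text(TWO_ATOM_PDB)
        st = gemmi.read_pdb(str(p))
        st.setup_entities()
        cif = tmp_path / "two.cif"
        st.make_mmcif_document().write_file(str(cif))
        s = parse_structure(cif, format="mmcif")
        assert len(s.atoms) == 2

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_structure(tmp_path / "nope.pdb")

    def test_garbage_is_a_parse_error(self, tmp_path):
        p = tmp_path / "bad.cif"
        p.write_text("this is not a structure\n")
        with pytest.raises(Exception):
            s = parse_structure(p, format="mmcif")
            assert s.atoms  # must not silently return an empty structure


def _two_residue_structure(distance: float) -> Structure:
    return Structure(atoms=[
        Atom("A", 1, "", "GLY", "CA", "C", 1.0, (0.0, 0.0, 0.0)),
        Atom("B", 1, "", "ALA", "CA", "C", 1.0, (distance, 0.0, 0.0)),
    ])


class TestContacts:
    def test_pair_inside_cutoff(self):
        iface = contact_residues(_two_residue_structure(3.5), "A", "B")
        assert [r.residue_number for r in iface.residues_a] == [1]
        assert [r.residue_number for r in iface.residues_partner] == [1]
        assert iface.min_distances_a[iface.residues_a[0]] == pytest.approx(3.5)

    def test_exact_cutoff_is_excluded(self):
        iface = contact_residues(_two_residue_structure(4.0), "A", "B")
        assert iface.residues_a == [] and iface.residues_partner == []

    def test_no_contacts_is_empty_not_error(self):
        iface = contact_residues(_two_residue_structure(10.0), "A", "B")
        assert iface.residues_a == []

    def test_missing_chain_raises(self):
        with pytest.raises(ValueError, match="chain"):
            contact_residues(_two_residue_structure(3.0), "A", "Z")

    def test_hydrogens_ignored_when_heavy_only(self):
        s = Structure(atoms=[
            Atom("A", 1, "", "GLY", "CA", "C", 1.0, (0.0, 0.0, 0.0)),
            Atom("A", 1, "", "GLY", "H", "H", 1.0, (4.5, 0.0, 0.0)),
            Atom("B", 1, "", "ALA", "CA", "C", 1.0, (6.0, 0.0, 0.0)),
            Atom("B", 1, "", "ALA", "H", "H", 1.0, (5.0, 0.0, 0.0)),
        ])
        assert contact_residues(s, "A", "B").residues_a == []
        with_h = contact_residues(s, "A", "B", heavy_only=False)
        assert [r.residue_number for r in with_h.residues_a] == [1]

    def test_ligand_selector(self, tmp_path):
        p = tmp_path / "lig.pdb"
        p.write_text(ALTLOC_PDB.replace("10.000", " 3.000"))
        s = parse_structure(p)
        iface = contact_residues(s, "A", "B:PLP")
        assert [r.residue_name for r in iface.residues_partner] == ["PLP"]

    @pytest.mark.parametrize("seed", range(200))
    def test_matches_brute_force_oracle(self, seed):
        """Planted contacts equal an O(n^2) all-pairs scan, 200 seeds."""
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(3, 9, size=2)
        k = int(rng.integers(0, min(n_a, n_b) + 1))
        bundle = make_toy_complex(int(n_a), int(n_b), k, seed=seed)
        iface = contact_residues(bundle.payload, "A", "B")
        got_a = [r.residue_number for r in iface.residues_a]
        got_b = [r.residue_number for r in iface.residues_partner]
        oracle_a, oracle_b = brute_force_contacts(bundle.payload, "A", "B")
        assert got_a == [r for r, _ in oracle_a] == bundle.truth["contact_residues_a"]
        assert got_b == [r for r, _ in oracle_b] == bundle.truth["contact_residues_b"]

    def test_monotone_in_cutoff(self):
        bundle = make_toy_complex(8, 8, 4, seed=11)
        sets = []
        for cutoff in (3.5, 4.0, 5.0):
            iface = contact_residues(bundle.payload, "A", "B", cutoff=cutoff)
            sets.append(set(iface.residues_a))
        assert sets[0] <= sets[1] <= sets[2]


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        s = Structure(atoms=[Atom("A", 1, "", "GLY", "CA", "C", 1.0, (0, 0, 0))])
        res = shrake_rupley_sasa(s, probe_radius=1.4, n_points=960)
        analytic = 4.0 * math.pi * (1.7 + 1.4) ** 2
        assert sum(res.per_atom_sasa.values()) == pytest.approx(analytic, rel=0.01)

    def test_coincident_atoms_count_one_sphere(self):
        s = Structure(atoms=[
            Atom("A", 1, "", "GLY", "CA", "C", 1.0, (0, 0, 0)),
            Atom("A", 1, "", "GLY", "CB", "C", 1.0, (0, 0, 0)),
        ])
        res = shrake_rupley_sasa(s)
        analytic = 4.0 * math.pi * (1.7 + 1.4) ** 2
        assert sum(res.per_atom_sasa.values()) == pytest.approx(analytic, rel=0.01)

    def test_enclosed_atom_has_zero_sasa(self):
        # shell of 30 carbons on a sphere of radius 3 A around the center:
        # every probe-inflated surface point of the central atom is covered
        golden = (1 + 5 ** 0.5) / 2
        atoms = [Atom("A", 1, "", "GLY", "CA", "C", 1.0, (0, 0, 0))]
        i = np.arange(30) + 0.5
        phi = np.arccos(1 - 2 * i / 30)
        theta = np.pi * (1 + golden) * i * 2
        for k, (p, t) in enumerate(zip(phi, theta)):
            xyz = 3.0 * np.array([np.sin(p) * np.cos(t),
                                  np.sin(p) * np.sin(t), np.cos(p)])
            atoms.append(Atom("A", 2 + k, "", "GLY", "CA", "C", 1.0, tuple(xyz)))
        res = shrake_rupley_sasa(Structure(atoms=atoms))
        assert res.per_atom_sasa[0] == pytest.approx(0.0, abs=1e-9)

    def test_complex_sasa_below_sum_of_chains(self):
        bundle = make_toy_complex(6, 6, 3, seed=5)
        s = bundle.payload
        total = sum(shrake_rupley_sasa(s).per_atom_sasa.values())
        parts = sum(sum(shrake_rupley_sasa(s, chain_subset=[c]).per_atom_sasa.values())
                    for c in ("A", "B"))
        assert total <= parts + 1e-6

    def test_quadrature_convergence(self):
        bundle = make_toy_complex(4, 4, 2, seed=2)
        s = bundle.payload
        coarse = sum(shrake_rupley_sasa(s, n_points=960).per_atom_sasa.values())
        fine = sum(shrake_rupley_sasa(s, n_points=1920).per_atom_sasa.values())
        assert abs(fine - coarse) / fine < 0.005

    def test_unknown_element_raises_with_atom_list(self):
        s = Structure(atoms=[Atom("A", 1, "", "UNK", "Q1", "Q", 1.0, (0, 0, 0))])
        with pytest.raises(ValueError, match="Q"):
            shrake_rupley_sasa(s)

    def test_cross_check_against_biotite(self):
        """Independent Shrake-Rupley implementation agrees on a toy complex."""
        import biotite.structure as bst

        bundle = make_toy_complex(6, 6, 3, seed=9)
        s = bundle.payload
        arr = bst.AtomArray(len(s.atoms))
        for i, a in enumerate(s.atoms):
            arr.coord[i] = a.coordinates
            arr.chain_id[i] = a.chain_id
            arr.res_id[i] = a.residue_number
            arr.res_name[i] = a.residue_name
            arr.atom_name[i] = a.atom_name
            arr.element[i] = a.element
        ref = float(np.nansum(bst.sasa(arr, probe_radius=1.4, point_number=1000,
                                       vdw_radii="Single")))
        ours = sum(shrake_rupley_sasa(s, n_points=960).per_atom_sasa.values())
        assert ours == pytest.approx(ref, rel=0.02)


class TestRelativeAndDeltaSasa:
    def test_relative_is_percent_of_reference(self):
        s = Structure(atoms=[Atom("A", 1, "", "GLY", "CA", "C", 1.0, (0, 0, 0))])
        res = shrake_rupley_sasa(s)
        rel = relative_sasa(res, ResidueId("A", 1, "", "GLY"))
        expected = 100.0 * sum(res.per_atom_sasa.values()) / \
            MAX_SASA_TABLES["tien2013_theoretical"]["GLY"]
        assert rel == pytest.approx(expected)

    def test_nonstandard_residue_raises(self):
        s = Structure(atoms=[Atom("A", 1, "", "PLP", "P", "P", 1.0, (0, 0, 0))])
        res = shrake_rupley_sasa(s)
        with pytest.raises(ValueError, match="PLP"):
            relative_sasa(res, ResidueId("A", 1, "", "PLP"))

    def test_delta_sasa_far_residue_unchanged_interface_drops(self):
        bundle = make_toy_complex(6, 6, 2, seed=4)
        table = delta_sasa_on_binding(bundle.payload, "A", ["B"], n_points=480)
        contact = set(bundle.truth["contact_residues_a"])
        for _, row in table.iterrows():
            assert row.sasa_complex <= row.sasa_free + 1e-6
            if row.resnum in contact:
                assert row.sasa_complex < row.sasa_free - 1.0
            else:
                # non-contact residues are > 6 A from chain B but can still
                # lose a little area to probe-mediated occlusion
                assert row.sasa_free - row.sasa_complex < 0.15 * row.sasa_free

    def test_empty_partner_set_raises(self):
        bundle = make_toy_complex(3, 3, 1, seed=1)
        with pytest.raises(ValueError, match="partner"):
            delta_sasa_on_binding(bundle.payload, "A", [])
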