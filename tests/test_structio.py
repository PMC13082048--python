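"""Structure I/O: parsing, altloc policy, selections, centers of mass."""

import numpy as np
import pytest

from rnapcollide.structio import (
    ResidueSelection,
    StructureModel,
    StructureError,
    read_selection_file,
    read_structure,
    residue_centers_of_mass,
    select_calpha,
    write_structure,
)

from conftest import make_atom, make_ca_chain


class TestReadStructure:
    def test_minimal_pdb_coordinates_bit_equal(self, minimal_pdb):
        model = read_structure(minimal_pdb)
        assert len(model) == 3
        np.testing.assert_array_equal(
            model.atoms[0].position, [11.104, 6.134, -6.504]
        )
        np.testing.assert_array_equal(
            model.atoms[2].position, [13.276, 5.262, -5.641]
        )
        assert [a.atom_name for a in model.atoms] == ["N", "CA", "C"]

    def test_pdb_and_mmcif_parse_identically(self, minimal_pdb, minimal_cif):
        pdb = read_structure(minimal_pdb, "pdb")
        cif = read_structure(minimal_cif, "mmcif")
        assert len(pdb) == len(cif)
        for a, b in zip(pdb.atoms, cif.atoms):
            assert (a.chain_id, a.residue_number, a.atom_name) == (
                b.chain_id,
                b.residue_number,
                b.atom_name,
            )
            np.testing.assert_allclose(a.position, b.position, atol=1e-6)

    def test_altloc_keeps_highest_occupancy(self, altloc_pdb):
        model = read_structure(altloc_pdb)
        assert len(model) == 1
        atom = model.atoms[0]
        assert atom.altloc == "A"
        assert atom.position[0] == pytest.approx(10.0)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(StructureError, match="no such file"):
            read_structure(tmp_path / "absent.pdb")

    def test_garbage_raises_parse_error(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("this is not a structure\n")
        with pytest.raises(StructureError):
            read_structure(bad)


class TestSelectCalpha:
    def _model(self, rng, start=3, end=27):
        return StructureModel("m", make_ca_chain("B", end - start + 1, rng))

    def test_range_count(self, rng):
        atoms = []
        for i, num in enumerate(range(3, 28)):
            atoms.append(make_atom("B", num, "CA", "C", (i * 3.8, 0, 0)))
        model = StructureModel("m", atoms)
        entries, skipped = select_calpha(
            model, ResidueSelection((("B", 3, 27),), "part")
        )
        assert len(entries) == 25
        assert skipped == []
        assert [n for _, n, _ in entries] == list(range(3, 28))

    def test_empty_intersection_errors(self, rng):
        model = StructureModel("m", [make_atom("B", 1, "CA")])
        with pytest.raises(StructureError, match="matches no residues"):
            select_calpha(model, ResidueSelection((("Z", 1, 5),), "none"))

    def test_gap_is_skip_reported(self):
        atoms = [
            make_atom("B", num, "CA", "C", (num * 3.8, num % 3, 0.5 * num))
            for num in range(5, 21)
            if num not in (10, 11, 12)
        ]
        # residues 10-12 present but without CA -> reported as skipped
        atoms += [make_atom("B", num, "CB", "C", (0, 0, num)) for num in (10, 11, 12)]
        model = StructureModel("m", atoms)
        entries, skipped = select_calpha(model, ResidueSelection((("B", 5, 20),), "p"))
        assert len(entries) == 16 - 3
        assert skipped == [("B", 10), ("B", 11), ("B", 12)]

    def test_order_deterministic(self, rng):
        atoms = make_ca_chain("B", 30, rng) + make_ca_chain("A", 10, rng)
        model = StructureModel("m", atoms)
        sel = ResidueSelection((("A", 2, 8), ("B", 1, 30)), "p")
        first, _ = select_calpha(model, sel)
        second, _ = select_calpha(model, sel)
        assert [(c, n) for c, n, _ in first] == [(c, n) for c, n, _ in second]
        assert [(c, n) for c, n, _ in first][:3] == [("A", 2), ("A", 3), ("A", 4)]


class TestCentersOfMass:
    def test_symmetric_pair(self):
        model = StructureModel(
            "m",
            [
                make_atom("X", 1, "C1", "C", (0, 0, 0)),
                make_atom("X", 1, "C2", "C", (2, 0, 0)),
            ],
        )
        [(key, com)] = residue_centers_of_mass(model, ResidueSelection((("X", 1, 1),)))
        np.testing.assert_allclose(com, [1, 0, 0])

    def test_mass_weighted_carbon_oxygen(self):
        model = StructureModel(
            "m",
            [
                make_atom("X", 1, "C1", "C", (0, 0, 0)),
                make_atom("X", 1, "O1", "O", (1, 0, 0)),
            ],
        )
        sel = ResidueSelection((("X", 1, 1),))
        [(_, weighted)] = residue_centers_of_mass(model, sel, mass_weighted=True)
        # hand-computed: 15.999 / (12.011 + 15.999)
        assert weighted[0] == pytest.approx(15.999 / (12.011 + 15.999), abs=1e-12)
        [(_, unweighted)] = residue_centers_of_mass(model, sel, mass_weighted=False)
        np.testing.assert_allclose(unweighted, [0.5, 0, 0])

    def test_hydrogens_excluded_by_default(self):
        model = StructureModel(
            "m",
            [
                make_atom("X", 1, "C1", "C", (0, 0, 0)),
                make_atom("X", 1, "H1", "H", (100, 0, 0)),
            ],
        )
        sel = ResidueSelection((("X", 1, 1),))
        [(_, com)] = residue_centers_of_mass(model, sel)
        np.testing.assert_allclose(com, [0, 0, 0])
        [(_, com_h)] = residue_centers_of_mass(model, sel, include_hydrogens=True)
        assert com_h[0] > 0

    def test_union_com_is_mass_weighted_combination(self, rng):
        """COM over several residues equals the mass-weighted mix of per-residue COMs."""
        atoms = []
        masses = []
        for num in range(1, 6):
            for j in range(rng.integers(2, 6)):
                el = ["C", "N", "O", "P"][rng.integers(0, 4)]
                a = make_atom("X", num, f"{el}{j+1}", el, rng.normal(size=3) * 5)
                atoms.append(a)
        model = StructureModel("m", atoms)
        sel = ResidueSelection((("X", 1, 5),))
        per_res = residue_centers_of_mass(model, sel)
        res_mass = {
            num: sum(a.mass for a in model.atoms_of("X", num)) for num in range(1, 6)
        }
        combined = sum(
            res_mass[key[1]] * com for key, com in per_res
        ) / sum(res_mass.values())
        total = sum(a.mass * a.position for a in atoms) / sum(a.mass for a in atoms)
        np.testing.assert_allclose(combined, total, atol=1e-10)

    def test_empty_residue_errors(self):
        model = StructureModel("m", [make_atom("X", 1, "H1", "H")])
        with pytest.raises(StructureError, match="no qualifying atoms"):
            residue_centers_of_mass(model, ResidueSelection((("X", 1, 1),)))


class TestWriteStructure:
    def test_round_trip_within_pdb_precision(self, rng, tmp_path):
        model = StructureModel("m", make_ca_chain("A", 5, rng))
        out = tmp_path / "out.pdb"
        write_structure(model, out)
        back = read_structure(out)
        assert len(back) == len(model)
        for a, b in zip(model.atoms, back.atoms):
            assert (a.chain_id, a.residue_number, a.atom_name) == (
                b.chain_id,
                b.residue_number,
                b.atom_name,
            )
            np.testing.assert_allclose(a.position, b.position, atol=1e-3)

    def test_read_write_read_idempotent(self, minimal_pdb, tmp_path):
        first = read_structure(minimal_pdb)
        out1 = tmp_path / "a.pdb"
        write_structure(first, out1)
        second = read_structure(out1)
        out2 = tmp_path / "b.pdb"
        write_structure(second, out2)
        third = read_structure(out2)
        for a, b in zip(second.atoms, third.atoms):
            np.testing.assert_array_equal(a.position, b.position)

    def test_long_chain_ids_renamed_with_mapping(self, tmp_path):
        model = StructureModel(
            "m",
            [
                make_atom("alpha", 1, "CA", "C", (0, 0, 0)),
                make_atom("alpha", 2, "CA", "C", (3.8, 1, 0)),
                make_atom("beta", 1, "CA", "C", (0, 5, 2)),
            ],
        )
        out = tmp_path / "renamed.pdb"
        mapping = write_structure(model, out)
        assert set(mapping) == {"alpha", "beta"}
        assert all(len(v) <= 2 for v in mapping.values())
        back = read_structure(out)
        assert set(back.chains) == set(mapping.values())

    def test_empty_model_write_errors(self, tmp_path):
        with pytest.raises(StructureError, match="empty"):
            write_structure(StructureModel("m", []), tmp_path / "x.pdb")


class TestSelections:
    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError, match="start > end"):
            ResidueSelection((("A", 10, 5),))

    def test_overlapping_parts_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            ResidueSelection((("A", 1, 10), ("A", 5, 20)))

    def test_selection_file_roundtrip(self, tmp_path):
        path = tmp_path / "sel.txt"
        path.write_text("# core\nB 3 27\nB 142 152\nA all\n")
        sel = read_selection_file(path, "core")
        assert sel.parts == (("B", 3, 27), ("B", 142, 152), ("A", None, None))
        assert sel.contains("A", 99999)
        assert sel.contains("B", 150)
        assert not sel.contains("B", 200)
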