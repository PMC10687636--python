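import math

import numpy as np
import pytest

from cpikit.interactions import (
    GeometryParams,
    atom_distance,
    detect_interactions,
    interaction_table,
    parse_structure,
    write_interactions_tsv,
)

from conftest import build_pdb, hexagon_ring, pdb_atom_line, phe_ring_atoms


def hbond_atoms():
    # Ser OG donor (chain A) to backbone O acceptor (chain B) at 2.9 A
    return [
        ("OG", "SER", "A", 1, 0.0, 0.0, 0.0, "O"),
        ("O", "GLY", "B", 1, 2.9, 0.0, 0.0, "O"),
    ]


def attractive_atoms():
    # Lys NZ (chain A) to Asp OD1 (chain B) at 4.0 A (beyond hbond cutoff)
    return [
        ("NZ", "LYS", "A", 1, 0.0, 0.0, 0.0, "N"),
        ("OD1", "ASP", "B", 1, 4.0, 0.0, 0.0, "O"),
    ]


def pipi_atoms():
    # two perpendicular Phe rings, centroids 5.0 A apart
    return phe_ring_atoms("A", 1, (0, 0, 0), normal="z") + \
        phe_ring_atoms("B", 1, (5, 0, 0), normal="y")


def pialkyl_atoms():
    # Phe ring (chain A) and Ala CB (chain B) 4.0 A from the centroid
    return phe_ring_atoms("A", 1, (0, 0, 0), normal="z") + [
        ("CB", "ALA", "B", 1, 4.0, 0.0, 0.0, "C"),
    ]


class TestParse:
    def test_minimal_two_atoms(self, tmp_path):
        model = parse_structure(build_pdb(hbond_atoms(), tmp_path / "m.pdb"))
        assert len(model.atoms) == 2
        assert model.chains == ["A", "B"]

    def test_multi_model_takes_first(self, tmp_path):
        lines = ["MODEL        1",
                 pdb_atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C"),
                 "ENDMDL",
                 "MODEL        2",
                 pdb_atom_line(2, "CA", "GLY", "A", 1, 9, 9, 9, "C"),
                 pdb_atom_line(3, "CB", "ALA", "A", 2, 9, 9, 9, "C"),
                 "ENDMDL"]
        path = tmp_path / "nmr.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        model = parse_structure(str(path))
        assert len(model.atoms) == 1
        assert model.atoms[0].coord == (0.0, 0.0, 0.0)

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        lines = [
            pdb_atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C", altloc="A", occupancy=0.4),
            pdb_atom_line(2, "CA", "GLY", "A", 1, 1, 0, 0, "C", altloc="B", occupancy=0.6),
        ]
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        model = parse_structure(str(path))
        assert len(model.atoms) == 1
        assert model.atoms[0].coord[0] == 1.0

    def test_no_atoms_errors(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER    EMPTY\nEND\n")
        with pytest.raises(ValueError, match="no ATOM records"):
            parse_structure(str(path))

    def test_malformed_coordinate_reports_line(self, tmp_path):
        good = pdb_atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C")
        bad = good[:30] + "   abc  " + good[38:]
        path = tmp_path / "bad.pdb"
        path.write_text(good + "\n" + bad + "\nEND\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_structure(str(path))


class TestAtomDistance:
    def test_coincident(self, tmp_path):
        atoms = [("OG", "SER", "A", 1, 1.0, 1.0, 1.0, "O"),
                 ("O", "GLY", "B", 1, 1.0, 1.0, 1.0, "O")]
        model = parse_structure(build_pdb(atoms, tmp_path / "m.pdb"))
        assert atom_distance(model, "A:SER1:OG", "B:GLY1:O") == 0.00

    def test_3_4_5_triangle(self, tmp_path):
        atoms = [("OG", "SER", "A", 1, 0.0, 0.0, 0.0, "O"),
                 ("O", "GLY", "B", 1, 3.0, 4.0, 0.0, "O")]
        model = parse_structure(build_pdb(atoms, tmp_path / "m.pdb"))
        assert atom_distance(model, "A:SER1:OG", "B:GLY1:O") == 5.00

    def test_unresolved_selector_named(self, tmp_path):
        model = parse_structure(build_pdb(hbond_atoms(), tmp_path / "m.pdb"))
        with pytest.raises(ValueError, match="A:ARG9:NH1"):
            atom_distance(model, "A:ARG9:NH1", "B:GLY1:O")


class TestDetect:
    @pytest.mark.parametrize("atoms,expected_type,expected_dist", [
        (hbond_atoms(), "hbond", 2.90),
        (attractive_atoms(), "attractive_charge", 4.00),
        (pipi_atoms(), "pi_pi_t_shaped", 5.00),
        (pialkyl_atoms(), "pi_alkyl", 4.00),
    ])
    def test_single_interaction_fixtures(self, tmp_path, atoms, expected_type,
                                         expected_dist):
        model = parse_structure(build_pdb(atoms, tmp_path / "m.pdb"))
        records = detect_interactions(model, "A", "B")
        assert len(records) == 1
        assert records[0].type == expected_type
        assert records[0].distance == expected_dist

    def test_roles(self, tmp_path):
        model = parse_structure(build_pdb(hbond_atoms(), tmp_path / "m.pdb"))
        record = detect_interactions(model, "A", "B")[0]
        assert record.roles == ("donor", "acceptor")
        assert record.from_sel == "A:SER1:OG"
        assert record.to_sel == "B:GLY1:O"

    def test_rigid_motion_invariance(self, tmp_path):
        atoms = (hbond_atoms() + attractive_atoms() + pipi_atoms() +
                 pialkyl_atoms()[6:])
        # merge fixtures into distinct residues to avoid key collisions
        merged = []
        for i, (name, resname, chain, _resseq, x, y, z, elem) in enumerate(atoms):
            resseq = {"OG": 1, "O": 2, "NZ": 3, "OD1": 4, "CB": 7}.get(name, 0)
            if resname == "PHE":
                resseq = 5 if chain == "A" else 6
            merged.append((name, resname, chain, resseq, x, y, z, elem))
        model = parse_structure(build_pdb(merged, tmp_path / "orig.pdb"))
        base = detect_interactions(model, "A", "B")
        assert base, "fixture must produce interactions"

        theta = 0.7
        rot = np.array([
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ]) @ np.array([
            [1, 0, 0],
            [0, math.cos(0.3), -math.sin(0.3)],
            [0, math.sin(0.3), math.cos(0.3)],
        ])
        shift = np.array([11.0, -7.0, 3.0])
        moved = [
            (name, resname, chain, resseq,
             *(rot @ np.array([x, y, z]) + shift), elem)
            for name, resname, chain, resseq, x, y, z, elem in merged
        ]
        model2 = parse_structure(build_pdb(moved, tmp_path / "moved.pdb"))
        transformed = detect_interactions(model2, "A", "B")
        assert [(r.type, r.from_sel, r.to_sel, r.distance) for r in base] == \
               [(r.type, r.from_sel, r.to_sel, r.distance) for r in transformed]

    def test_distances_within_cutoffs(self, tmp_path):
        params = GeometryParams()
        atoms = pipi_atoms() + pialkyl_atoms()[6:]  # rings + ALA CB
        model = parse_structure(build_pdb(atoms, tmp_path / "m.pdb"))
        for record in detect_interactions(model, "A", "B", params):
            assert 0 < record.distance <= params.cutoff(record.type)

    def test_pipi_angle_window_excludes_parallel(self, tmp_path):
        atoms = phe_ring_atoms("A", 1, (0, 0, 0), normal="z") + \
            phe_ring_atoms("B", 1, (5, 0, 0), normal="z")
        model = parse_structure(build_pdb(atoms, tmp_path / "m.pdb"))
        assert detect_interactions(model, "A", "B") == []

    def test_pipi_centroid_distance_hand_computed(self, tmp_path):
        center_a = np.array([0.0, 0.0, 0.0])
        center_b = np.array([3.0, 4.0, 0.0])
        expected = float(np.linalg.norm(center_b - center_a))
        atoms = phe_ring_atoms("A", 1, center_a, normal="z") + \
            phe_ring_atoms("B", 1, center_b, normal="x")
        model = parse_structure(build_pdb(atoms, tmp_path / "m.pdb"))
        records = detect_interactions(model, "A", "B")
        assert len(records) == 1
        assert records[0].distance == round(expected, 2)

    def test_cterminal_oxt_counts_as_carboxylate(self, tmp_path):
        atoms = [
            ("NH1", "ARG", "A", 127, 0.0, 0.0, 0.0, "N"),
            ("O", "VAL", "B", 38, 4.2, 0.0, 0.0, "O"),
            ("OXT", "VAL", "B", 38, 4.5, 1.0, 0.0, "O"),
        ]
        model = parse_structure(build_pdb(atoms, tmp_path / "m.pdb"))
        records = detect_interactions(model, "A", "B")
        charges = [r for r in records if r.type == "attractive_charge"]
        assert {r.to_sel for r in charges} == {"B:VAL38:O", "B:VAL38:OXT"}

    def test_his_positive_flag(self, tmp_path):
        atoms = [
            ("NE2", "HIS", "A", 1, 0.0, 0.0, 0.0, "N"),
            ("OD1", "ASP", "B", 1, 3.0, 0.0, 0.0, "O"),
        ]
        model = parse_structure(build_pdb(atoms, tmp_path / "m.pdb"))
        off = detect_interactions(model, "A", "B")
        assert [r.type for r in off] == ["hbond"]  # NE2 is still a donor
        on = detect_interactions(model, "A", "B", GeometryParams(his_positive=True))
        assert "attractive_charge" in {r.type for r in on}

    def test_missing_chain_errors(self, tmp_path):
        model = parse_structure(build_pdb(hbond_atoms(), tmp_path / "m.pdb"))
        with pytest.raises(ValueError, match="'Z'"):
            detect_interactions(model, "A", "Z")

    def test_sorted_by_type_then_distance(self, tmp_path):
        atoms = (hbond_atoms() + attractive_atoms())
        merged = []
        for name, resname, chain, _resseq, x, y, z, elem in atoms:
            resseq = {"OG": 1, "O": 2, "NZ": 3, "OD1": 4}[name]
            merged.append((name, resname, chain, resseq, x, y, z, elem))
        model = parse_structure(build_pdb(merged, tmp_path / "m.pdb"))
        records = detect_interactions(model, "A", "B")
        types = [r.type for r in records]
        assert types == sorted(
            types, key=["hbond", "attractive_charge", "pi_pi_t_shaped",
                        "pi_alkyl"].index)


class TestTable:
    def test_empty_gives_header_only(self, tmp_path):
        out = tmp_path / "t.tsv"
        write_interactions_tsv([], out)
        lines = out.read_text().strip().splitlines()
        assert lines == ["Interaction\tDistance_A\tType\tFrom_role\tTo_role"]

    def test_rows_in_input_order(self, tmp_path):
        model = parse_structure(build_pdb(hbond_atoms(), tmp_path / "m.pdb"))
        records = detect_interactions(model, "A", "B")
        table = interaction_table(records)
        assert list(table["Type"]) == ["hbond"]
        assert list(table["Distance_A"]) == ["2.90"]
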