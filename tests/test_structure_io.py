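"""Parsing, receptor/ligand partitioning and curation rules."""

import numpy as np
import pytest

from voxbind.structure import (
    Atom, CurationConfig, ParseError, infer_element, min_contact_distance,
    parse_pdb, partition_complex, passes_curation,
)
from tests.conftest import pdb_line


def make_pdb(lines):
    return "\n".join(lines) + "\nEND\n"


def rna_chain(n_res, chain="A", start_serial=1, spacing=6.0):
    """Minimal RNA chain: P, C1', N1 per residue, spaced along x."""
    lines = []
    serial = start_serial
    for i in range(n_res):
        x = i * spacing
        for name, el, dy in (("P", "P", 0.0), ("C1'", "C", 1.5), ("N1", "N", 3.0)):
            lines.append(pdb_line("ATOM", serial, name, "A", chain, i + 1,
                                  x, dy, 0.0, el))
            serial += 1
    return lines, serial


class TestParse:
    def test_two_atom_records_copy_fields(self):
        text = make_pdb([
            pdb_line("ATOM", 1, "P", "A", "A", 1, 1.0, 2.0, 3.0, "P"),
            pdb_line("HETATM", 2, "C1", "LIG", "B", 9, -4.5, 0.25, 8.125, "C"),
        ])
        s = parse_pdb(text)
        assert len(s.atoms) == 2
        np.testing.assert_allclose(s.atoms[0].coords, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(s.atoms[1].coords, [-4.5, 0.25, 8.125])
        assert s.atoms[0].element == "P"
        assert s.atoms[1].is_hetero and not s.atoms[0].is_hetero

    def test_blank_element_inferred_and_matches_reference_parser(self):
        """Element inference from atom names agrees with Biopython on the
        same fixture when columns 77-78 are blank."""
        text = make_pdb([
            pdb_line("ATOM", 1, "C1'", "A", "A", 1, 0.0, 0.0, 0.0),
            pdb_line("ATOM", 2, "N9", "A", "A", 1, 1.0, 0.0, 0.0),
            pdb_line("ATOM", 3, "OP1", "A", "A", 1, 2.0, 0.0, 0.0),
        ])
        s = parse_pdb(text)
        ours = [a.element for a in s.atoms]
        assert ours == ["C", "N", "O"]

        Bio = pytest.importorskip("Bio.PDB")
        import io, warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            struct = Bio.PDBParser(QUIET=True).get_structure("x", io.StringIO(text))
        ref = [a.element for a in struct.get_atoms()]
        assert ours == ref

    @pytest.mark.parametrize("name,expected", [
        (" C1'", "C"), ("CL1", "Cl"), ("BR", "Br"), ("N9", "N"), ("MG", "Mg"),
    ])
    def test_element_inference_rules(self, name, expected):
        assert infer_element(name) == expected

    def test_remark_only_is_parse_error(self):
        with pytest.raises(ParseError):
            parse_pdb("REMARK nothing here\nEND\n")

    def test_bad_coordinate_names_line(self):
        good = pdb_line("ATOM", 1, "P", "A", "A", 1, 0.0, 0.0, 0.0, "P")
        bad = good.replace(f"{0.0:8.3f}", "   xx.yy", 1)
        with pytest.raises(ParseError, match="line 2"):
            parse_pdb(make_pdb([good, bad]))


class TestPartition:
    def build(self):
        lines, serial = rna_chain(10)
        # 4 hydrogens on the RNA
        for j in range(4):
            lines.append(pdb_line("ATOM", serial, f"H{j+1}", "A", "A", 1,
                                  0.1 * j, -1.0, 0.0, "H"))
            serial += 1
        # ligand: 4 heavy + 2 H, plus a water
        for j in range(4):
            lines.append(pdb_line("HETATM", serial, f"C{j+1}", "LIG", "B", 101,
                                  1.0 + j, 3.0, 0.5, "C"))
            serial += 1
        for j in range(2):
            lines.append(pdb_line("HETATM", serial, f"H{j+1}", "LIG", "B", 101,
                                  1.0, 3.5, 0.5, "H"))
            serial += 1
        lines.append(pdb_line("HETATM", serial, "O", "HOH", "B", 201,
                              9.0, 9.0, 9.0, "O"))
        return parse_pdb(make_pdb(lines))

    def test_heavy_atom_partition(self):
        pair = partition_complex(self.build(), "LIG")
        assert len(pair.rna_atoms) == 30  # 10 residues x 3 heavy atoms
        assert len(pair.ligand_atoms) == 4
        assert all(a.element not in ("H", "D") for a in pair.rna_atoms)
        assert all(a.element not in ("H", "D") for a in pair.ligand_atoms)

    def test_waters_never_in_ligand(self):
        pair = partition_complex(self.build(), "LIG")
        assert all(a.residue_name != "HOH" for a in pair.ligand_atoms)

    def test_missing_ligand_id_errors(self):
        with pytest.raises(ValueError, match="XYZ"):
            partition_complex(self.build(), "XYZ")


class TestCuration:
    def complex_with(self, n_res, ligand_dist=3.5, lig_atoms=2, lig_name="LIG",
                     extra_lines=()):
        lines, serial = rna_chain(n_res)
        # nearest RNA atom is N1 at y=3.0; ligand sits ligand_dist above it
        for j in range(lig_atoms):
            lines.append(pdb_line("HETATM", serial, f"C{j+1}", lig_name, "B",
                                  101, 0.0, 3.0 + ligand_dist + 1.4 * j, 0.0,
                                  "C"))
            serial += 1
        lines.extend(extra_lines)
        s = parse_pdb(make_pdb(lines))
        return partition_complex(s, lig_name), s

    def test_short_rna_rejected(self):
        pair, s = self.complex_with(8)
        ok, reason = passes_curation(pair, s)
        assert not ok and reason == "min_rna_length"

    def test_ten_nucleotides_pass(self):
        pair, s = self.complex_with(10)
        assert passes_curation(pair, s) == (True, "ok")

    @pytest.mark.parametrize("dist,expected", [(3.5, True), (4.5, False)])
    def test_contact_distance_rule(self, dist, expected):
        pair, s = self.complex_with(10, ligand_dist=dist)
        ok, reason = passes_curation(pair, s)
        assert ok is expected
        if not ok:
            assert reason == "contact"

    def test_single_atom_ion_rejected(self):
        pair, s = self.complex_with(10, lig_atoms=1, lig_name="MG")
        ok, reason = passes_curation(pair, s)
        assert not ok and reason == "ion"

    def test_artifact_ligand_rejected(self):
        pair, s = self.complex_with(10, lig_atoms=3, lig_name="GOL")
        ok, reason = passes_curation(pair, s)
        assert not ok and reason == "artifact"

    def test_protein_chain_rejected(self):
        extra = [pdb_line("ATOM", 900 + j, "CA", "ALA", "C", j + 1,
                          30.0 + j, 0.0, 0.0, "C") for j in range(3)]
        pair, s = self.complex_with(10, extra_lines=extra)
        ok, reason = passes_curation(pair, s)
        assert not ok and reason == "protein"

    def test_order_independent(self):
        pair, s = self.complex_with(10)
        rng = np.random.default_rng(0)
        for _ in range(3):
            atoms = list(s.atoms)
            rng.shuffle(atoms)
            shuffled = type(s)(atoms=atoms, source_id=s.source_id)
            pair2 = partition_complex(shuffled, "LIG")
            assert passes_curation(pair2, shuffled) == passes_curation(pair, s)

    def test_min_contact_distance_value(self):
        pair, _ = self.complex_with(10, ligand_dist=3.5)
        assert min_contact_distance(pair) == pytest.approx(3.5)


def test_curation_config_validation():
    with pytest.raises(ValueError):
        CurationConfig(contact_cutoff=0.0)
    with pytest.raises(ValueError):
        CurationConfig(min_rna_length=0)
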