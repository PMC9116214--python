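"""Structure parsing, preparation filters and the feature alphabets."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sfct import (
    ELEMENT_CLASSES,
    RESIDUE_CLASSES,
    classify_element,
    classify_residue,
    generate_toy_complex,
    read_ligand_poses,
    read_receptor,
    write_poses_sdf,
    write_receptor_pdb,
)
from sfct.exceptions import EmptyStructureError, StructureParseError, TopologyError
from sfct.synthetic import generate_decoys, DecoySpec

TOY_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   ASP A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  ASP A   2       3.988   2.835   0.000  1.00  0.00           C
ATOM      7  H   ASP A   2       3.850   1.000   0.500  1.00  0.00           H
ATOM      8  N   LYS A   3       5.332   2.836   0.000  1.00  0.00           N
ATOM      9  CA  LYS A   3       6.088   4.075   0.000  1.00  0.00           C
HETATM   10  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O
HETATM   11 ZN    ZN A 102       8.000   8.000   8.000  1.00  0.00          ZN
END
"""

TOY_PDBQT_RECEPTOR = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00    -0.35 N
ATOM      2  HN  SER A   1       0.500   0.800   0.000  1.00  0.00     0.16 HD
ATOM      3  CA  SER A   1       1.458   0.000   0.000  1.00  0.00     0.19 C
ATOM      4  OG  SER A   1       2.100   1.300   0.500  1.00  0.00    -0.39 OA
"""

VINA_PDBQT = """\
MODEL 1
REMARK VINA RESULT:    -8.5      0.000      0.000
ATOM      1  C1  LIG L   1       0.000   0.000   0.000  1.00  0.00     0.10 C
ATOM      2  O1  LIG L   1       1.400   0.000   0.000  1.00  0.00    -0.30 OA
ATOM      3  N1  LIG L   1       2.100   1.200   0.000  1.00  0.00    -0.20 NA
ENDMDL
MODEL 2
REMARK VINA RESULT:    -7.1      1.953      3.210
ATOM      1  C1  LIG L   1       0.500   0.000   0.000  1.00  0.00     0.10 C
ATOM      2  O1  LIG L   1       1.900   0.100   0.000  1.00  0.00    -0.30 OA
ATOM      3  N1  LIG L   1       2.600   1.300   0.000  1.00  0.00    -0.20 NA
ENDMDL
"""

BENZENE_MOL2 = """\
@<TRIPOS>MOLECULE
benzene
 6 6 1
SMALL
NO_CHARGES
@<TRIPOS>ATOM
      1 C1          1.3970    0.0000    0.0000 C.ar
      2 C2          0.6985    1.2098    0.0000 C.ar
      3 C3         -0.6985    1.2098    0.0000 C.ar
      4 C4         -1.3970    0.0000    0.0000 C.ar
      5 C5         -0.6985   -1.2098    0.0000 C.ar
      6 C6          0.6985   -1.2098    0.0000 C.ar
@<TRIPOS>BOND
     1    1    2 ar
     2    2    3 ar
     3    3    4 ar
     4    4    5 ar
     5    5    6 ar
     6    6    1 ar
"""


class TestReadReceptor:
    def test_waters_ions_and_hydrogens_removed(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(TOY_PDB)
        protein = read_receptor(path)
        assert len(protein.residues) == 3
        names = {a.residue_name for a in protein.atoms}
        assert "HOH" not in names and "ZN" not in names
        assert all(a.element.upper() != "H" for a in protein.atoms)
        assert len(protein) == 8  # 9 protein records minus the hydrogen

    def test_pdbqt_polar_hydrogens_dropped(self, tmp_path):
        path = tmp_path / "rec.pdbqt"
        path.write_text(TOY_PDBQT_RECEPTOR)
        protein = read_receptor(path)
        assert [a.element for a in protein.atoms] == ["N", "C", "O"]

    def test_water_only_file_is_empty_structure(self, tmp_path):
        path = tmp_path / "wet.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
        )
        with pytest.raises(EmptyStructureError):
            read_receptor(path)

    def test_missing_file_and_bad_record_raise_parse_errors(self, tmp_path):
        with pytest.raises(StructureParseError):
            read_receptor(tmp_path / "nope.pdb")
        bad = tmp_path / "bad.pdb"
        bad.write_text("ATOM      1  N   GLY A   1      xx.000   0.000\n")
        with pytest.raises(StructureParseError, match="line 1"):
            read_receptor(bad)

    def test_pdb_round_trip_preserves_classes_and_coords(self, tmp_path, toy_complex):
        protein, _ = toy_complex
        path = tmp_path / "out.pdb"
        write_receptor_pdb(protein, path)
        back = read_receptor(path)
        assert len(back) == len(protein)
        assert [classify_residue(a.residue_name) for a in back.atoms] == [
            classify_residue(a.residue_name) for a in protein.atoms
        ]
        assert np.allclose(back.coords, protein.coords, atol=1e-3)


class TestReadLigandPoses:
    def test_sdf_conformers_keep_file_order_and_ids(self, tmp_path):
        _, native = generate_toy_complex(seed=5, n_residues=8, n_ligand_atoms=10)
        decoys, _ = generate_decoys(native, DecoySpec(n_decoys_per_native=9, seed=2))
        path = tmp_path / "poses.sdf"
        write_poses_sdf(decoys, path)
        poses = read_ligand_poses(path)
        assert len(poses) == 9
        assert [p.pose_id for p in poses] == [str(i) for i in range(1, 10)]
        assert np.allclose(poses[0].coords, decoys[0].coords, atol=1e-4)

    def test_vina_pdbqt_scores_captured_per_model(self, tmp_path):
        path = tmp_path / "out.pdbqt"
        path.write_text(VINA_PDBQT)
        poses = read_ligand_poses(path)
        assert [p.source_score for p in poses] == [-8.5, -7.1]
        assert [p.pose_id for p in poses] == ["1", "2"]
        assert poses[0].elements == ("C", "O", "N")
        assert len(poses[0].bonds) > 0  # perceived from distances

    def test_mol2_single_molecule_with_bonds(self, tmp_path):
        path = tmp_path / "benzene.mol2"
        path.write_text(BENZENE_MOL2)
        (pose,) = read_ligand_poses(path)
        assert len(pose) == 6
        assert len(pose.bonds) == 6

    def test_inconsistent_atom_counts_rejected(self, tmp_path):
        truncated = VINA_PDBQT.replace(
            "ATOM      3  N1  LIG L   1       2.600   1.300   0.000  1.00  0.00    -0.20 NA\n",
            "",
        )
        path = tmp_path / "bad.pdbqt"
        path.write_text(truncated)
        with pytest.raises(TopologyError):
            read_ligand_poses(path)


class TestAlphabets:
    def test_alphabet_sizes_are_fixed(self):
        assert len(RESIDUE_CLASSES) == 21
        assert len(ELEMENT_CLASSES) == 7

    @pytest.mark.parametrize(
        "name,expected",
        [("ASP", "ASP"), ("asp", "ASP"), ("MSE", "OTH"), ("xyz", "OTH"), ("HOH", "OTH")],
    )
    def test_residue_classification(self, name, expected):
        assert classify_residue(name) == expected

    @pytest.mark.parametrize(
        "symbol,expected",
        [("C", "C"), ("N", "N"), ("Cl", "HAL"), ("BR", "HAL"), ("I", "HAL"),
         ("Fe", "OTH"), ("Se", "OTH"), ("P", "P")],
    )
    def test_element_classification(self, symbol, expected):
        assert classify_element(symbol) == expected

    @given(st.text(min_size=0, max_size=4))
    def test_classification_is_total(self, text):
        assert classify_residue(text) in RESIDUE_CLASSES
        assert classify_element(text) in ELEMENT_CLASSES
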