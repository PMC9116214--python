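"""Contact-shell featurization against an independent brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sfct import (
    Atom,
    LigandPose,
    ProteinStructure,
    ShellScheme,
    feature_schema,
    featurize_complex,
    generate_toy_complex,
    shell_index,
)
from sfct.exceptions import EmptyStructureError

# --- independent oracle: its own alphabets, binning and double loop ---------

_ORACLE_RESIDUES = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL", "OTH",
]
_ORACLE_ELEMENTS = ["C", "N", "O", "S", "P", "HAL", "OTH"]


def _oracle_res(name):
    name = name.strip().upper()
    return name if name in _ORACLE_RESIDUES[:20] else "OTH"


def _oracle_elem(symbol):
    symbol = symbol.strip().upper()
    if symbol in ("C", "N", "O", "S", "P"):
        return symbol
    return "HAL" if symbol in ("F", "CL", "BR", "I") else "OTH"


def brute_force_featurize(protein, pose, scheme):
    """O(N·M) double loop with explicit per-shell interval checks."""
    counts = np.zeros(
        (len(_ORACLE_RESIDUES), len(_ORACLE_ELEMENTS), scheme.n_shells), dtype=int
    )
    for pa in protein.atoms:
        for la in pose.atoms:
            d = float(np.sqrt(np.sum((pa.coords - la.coords) ** 2)))
            for k in range(1, scheme.n_shells + 1):
                lo = scheme.origin + (k - 1) * scheme.shell_width
                hi = scheme.origin + k * scheme.shell_width
                if lo <= d < hi:
                    counts[
                        _ORACLE_RESIDUES.index(_oracle_res(pa.residue_name)),
                        _ORACLE_ELEMENTS.index(_oracle_elem(la.element)),
                        k - 1,
                    ] += 1
                    break
    return counts.ravel()


class TestShellIndex:
    @pytest.mark.parametrize(
        "distance,expected",
        [(0.0, 1), (1.4999, 1), (1.5, 2), (2.0, 2), (20.9999, 14), (21.0, None), (35.0, None)],
    )
    def test_default_scheme_boundaries(self, distance, expected):
        assert shell_index(distance) == expected

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            shell_index(-0.1)

    @given(st.floats(min_value=0.0, max_value=40.0, allow_nan=False))
    def test_matches_interval_definition(self, distance):
        scheme = ShellScheme()
        k = shell_index(distance, scheme)
        if distance >= scheme.max_distance:
            assert k is None
        else:
            lo = scheme.origin + (k - 1) * scheme.shell_width
            assert lo <= distance < lo + scheme.shell_width


class TestFeatureSchema:
    def test_default_ordering_and_length(self):
        schema = feature_schema()
        assert len(schema) == 21 * 7 * 14 == 2058
        assert schema[0] == ("ALA", "C", 1)
        assert schema[13] == ("ALA", "C", 14)
        assert schema[14] == ("ALA", "N", 1)
        assert schema[-1] == ("OTH", "OTH", 14)

    def test_two_shell_scheme_length(self):
        assert len(feature_schema(ShellScheme(n_shells=2))) == 294


def _single_atom_pose(coords, element="C"):
    return LigandPose([Atom(element, np.asarray(coords, float), "LIG", 1, "L", True)])


class TestFeaturizeComplex:
    def test_glycine_worked_example(self):
        # One GLY (N, CA, C, O) with a ligand carbon at hand-picked distances
        # 2.9, 2.0, 3.2, 4.1 -> two pairs in shell 2 ([1.5, 3.0)) and two in
        # shell 3 ([3.0, 4.5)).
        protein = ProteinStructure([
            Atom("N", [2.9, 0.0, 0.0], "GLY", 1, "A"),
            Atom("C", [0.0, 2.0, 0.0], "GLY", 1, "A"),  # CA
            Atom("C", [0.0, 0.0, 3.2], "GLY", 1, "A"),
            Atom("O", [-4.1, 0.0, 0.0], "GLY", 1, "A"),
        ])
        pose = _single_atom_pose([0.0, 0.0, 0.0])
        fv = featurize_complex(protein, pose)
        expected = np.zeros(2058, dtype=np.int64)
        schema = feature_schema()
        expected[schema.index(("GLY", "C", 2))] = 2
        expected[schema.index(("GLY", "C", 3))] = 2
        assert np.array_equal(fv.counts, expected)

    def test_far_ligand_gives_all_zero_vector(self, toy_complex):
        protein, ligand = toy_complex
        far = ligand.with_coords(ligand.coords + 500.0)
        fv = featurize_complex(protein, far)
        assert len(fv) == 2058 and fv.counts.sum() == 0

    def test_matches_bruteforce_on_random_complexes(self):
        rng = np.random.default_rng(42)
        scheme = ShellScheme()
        for _ in range(30):
            protein, ligand = generate_toy_complex(
                seed=int(rng.integers(0, 2**31 - 1)),
                n_residues=int(rng.integers(5, 31)),
                n_ligand_atoms=int(rng.integers(5, 41)),
            )
            fast = featurize_complex(protein, ligand, scheme).counts
            assert np.array_equal(fast, brute_force_featurize(protein, ligand, scheme))

    def test_total_count_is_pair_census(self, toy_complex):
        protein, ligand = toy_complex
        fv = featurize_complex(protein, ligand)
        dists = np.linalg.norm(
            protein.coords[:, None, :] - ligand.coords[None, :, :], axis=2
        )
        assert fv.counts.sum() == int((dists < 21.0).sum())

    def test_rigid_motion_of_whole_complex_is_invariant(self, toy_complex):
        from scipy.spatial.transform import Rotation

        protein, ligand = toy_complex
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        shift = np.array([5.0, -3.0, 12.0])
        moved_protein = ProteinStructure([
            Atom(a.element, a.coords @ rot.T + shift, a.residue_name, a.residue_seq,
                 a.chain_id, a.is_hetero)
            for a in protein.atoms
        ])
        moved_ligand = ligand.with_coords(ligand.coords @ rot.T + shift)
        assert np.array_equal(
            featurize_complex(protein, ligand).counts,
            featurize_complex(moved_protein, moved_ligand).counts,
        )

    def test_receding_ligand_never_gains_first_shell_contacts(self):
        # Protein strictly at x <= 0, ligand at x >= 1: translating the ligand
        # along +x increases every pairwise distance.
        protein = ProteinStructure([
            Atom("C", [-0.5 * i, 0.1 * i, 0.0], "ALA", i + 1, "A") for i in range(6)
        ])
        schema = feature_schema()
        shell1_bins = [i for i, (_, _, s) in enumerate(schema) if s == 1]
        pose = _single_atom_pose([1.2, 0.0, 0.0])
        previous = featurize_complex(protein, pose).counts[shell1_bins].sum()
        for step in (0.5, 1.0, 2.0, 5.0):
            moved = pose.with_coords(pose.coords + np.array([step, 0.0, 0.0]))
            current = featurize_complex(protein, moved).counts[shell1_bins].sum()
            assert current <= previous
            previous = current

    def test_empty_inputs_rejected(self, toy_complex):
        protein, ligand = toy_complex
        with pytest.raises(EmptyStructureError):
            LigandPose([])
        with pytest.raises(EmptyStructureError):
            ProteinStructure([])
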