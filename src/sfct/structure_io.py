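"""Receptor and ligand-pose I/O plus the residue/element feature alphabets.

Receptors are read from PDB (via Biopython) or PDBQT (AutoDock dialect,
parsed here because no maintained reader exists for it) into a
heavy-atom-only :class:`ProteinStructure`: waters, monatomic ions and
non-polymer hetero molecules are stripped, matching the usual docking
preparation in which water molecules and metal ions are removed before
featurization.  Ligand pose sets come from SDF/MOL2 (via RDKit) or
multi-model PDBQT files; every pose of one file must share a single
topology so that pose-vs-native RMSD needs no re-matching.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import EmptyStructureError, StructureParseError, TopologyError

# ---------------------------------------------------------------------------
# Feature alphabets
# ---------------------------------------------------------------------------

#: The 20 standard amino acids (alphabetical) plus the catch-all class.
STANDARD_RESIDUES: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
RESIDUE_CLASSES: tuple[str, ...] = STANDARD_RESIDUES + ("OTH",)

#: Ligand heavy-atom element classes; halogens are pooled.
ELEMENT_CLASSES: tuple[str, ...] = ("C", "N", "O", "S", "P", "HAL", "OTH")
_HALOGENS = frozenset({"F", "CL", "BR", "I"})

_RESIDUE_INDEX = {name: i for i, name in enumerate(RESIDUE_CLASSES)}
_ELEMENT_INDEX = {name: i for i, name in enumerate(ELEMENT_CLASSES)}

#: Residue names treated as water.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: Monatomic ions commonly deposited with complexes; removed on read.
ION_NAMES = frozenset({
    "NA", "K", "CL", "CA", "MG", "ZN", "MN", "FE", "FE2", "CO", "CU", "NI",
    "CD", "HG", "BR", "IOD", "F", "CS", "LI", "SR", "BA", "RB", "AL", "PB",
    "SO4", "PO4",  # common crystallization additives, never part of the chain
})


def classify_residue(residue_name: str) -> str:
    """Map a residue name onto the 21-letter residue alphabet.

    Standard amino-acid codes map to themselves (case-insensitively);
    everything else — non-standard residues, ligands, typos — maps to
    ``"OTH"``.  Total and deterministic.
    """
    name = residue_name.strip().upper()
    return name if name in _RESIDUE_INDEX and name != "OTH" else "OTH"


def classify_element(symbol: str) -> str:
    """Map an element symbol onto the 7-letter ligand element alphabet.

    C/N/O/S/P map to themselves, the halogens F/Cl/Br/I pool into
    ``"HAL"`` and anything else maps to ``"OTH"``.  Hydrogens never reach
    this function because all structures are heavy-atom only.
    """
    sym = symbol.strip().upper()
    if sym in ("C", "N", "O", "S", "P"):
        return sym
    if sym in _HALOGENS:
        return "HAL"
    return "OTH"


def residue_class_index(residue_name: str) -> int:
    return _RESIDUE_INDEX[classify_residue(residue_name)]


def element_class_index(symbol: str) -> int:
    return _ELEMENT_INDEX[classify_element(symbol)]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """One heavy atom with its residue context."""

    element: str
    coords: np.ndarray  # shape (3,), Å
    residue_name: str = "UNK"
    residue_seq: int = 0
    chain_id: str = "A"
    is_hetero: bool = False

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom coordinates must be a finite 3-vector, got {coords!r}")
        object.__setattr__(self, "coords", coords)


@dataclass
class ProteinStructure:
    """A receptor as an ordered heavy-atom list grouped into residues."""

    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError("protein structure has no heavy atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float array of atom coordinates in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def residue_class_indices(self) -> np.ndarray:
        """Per-atom index into :data:`RESIDUE_CLASSES`."""
        return np.array([residue_class_index(a.residue_name) for a in self.atoms], dtype=np.intp)

    @property
    def residues(self) -> dict[tuple[str, int], list[Atom]]:
        """Atoms grouped by (chain_id, residue_seq), in file order."""
        groups: dict[tuple[str, int], list[Atom]] = {}
        for atom in self.atoms:
            groups.setdefault((atom.chain_id, atom.residue_seq), []).append(atom)
        return groups


@dataclass
class LigandPose:
    """One ligand conformer: heavy atoms, bonds, and an identifier."""

    atoms: list[Atom]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)  # (i, j, order)
    pose_id: str = "1"
    source_score: float | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError(f"ligand pose {self.pose_id!r} has no heavy atoms")
        n = len(self.atoms)
        for i, j, _order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise TopologyError(f"bond ({i},{j}) out of range for {n} atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.atoms)

    def with_coords(self, coords: np.ndarray, pose_id: str | None = None) -> "LigandPose":
        """Copy of this pose with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise TopologyError(
                f"coordinate array shape {coords.shape} does not match {len(self.atoms)} atoms"
            )
        atoms = [
            Atom(a.element, c, a.residue_name, a.residue_seq, a.chain_id, a.is_hetero)
            for a, c in zip(self.atoms, coords)
        ]
        return LigandPose(atoms, list(self.bonds), pose_id or self.pose_id, self.source_score)


# ---------------------------------------------------------------------------
# Receptor reading
# ---------------------------------------------------------------------------

_AUTODOCK_TYPE_TO_ELEMENT = {
    "C": "C", "A": "C", "CG0": "C", "G0": "C",
    "N": "N", "NA": "N", "NS": "N",
    "O": "O", "OA": "O", "OS": "O",
    "S": "S", "SA": "S",
    "P": "P",
    "F": "F", "CL": "CL", "BR": "BR", "I": "I",
    "H": "H", "HD": "H", "HS": "H",
    "MG": "MG", "MN": "MN", "ZN": "ZN", "CA": "CA", "FE": "FE",
}


def _detect_format(path: Path, declared: str) -> str:
    if declared != "auto":
        return declared
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("pdb", "pdbqt", "sdf", "mol2", "ent"):
        return "pdb" if suffix == "ent" else suffix
    raise StructureParseError(f"cannot infer format from extension of {path}")


def _element_from_pdb_line(line: str) -> str:
    elem = line[76:78].strip() if len(line) >= 78 else ""
    if not elem:
        # Fall back to the atom-name columns; digits and whitespace stripped.
        name = line[12:16].strip().lstrip("0123456789")
        elem = name[:2] if name[:2].upper() in _HALOGENS else name[:1]
    return elem.capitalize()


def _parse_pdb_like_atoms(lines: Iterable[str], *, pdbqt: bool, source: str) -> list[Atom]:
    atoms: list[Atom] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            residue_name = line[17:20].strip() or "UNK"
            chain_id = line[21:22].strip() or "A"
            residue_seq = int(line[22:26].strip() or 0)
        except (ValueError, IndexError) as exc:
            raise StructureParseError(f"{source}: unparseable record at line {lineno}: {line.rstrip()!r}") from exc
        if pdbqt:
            # The AutoDock atom type is the trailing token (nominally columns
            # 78-79, but column drift is common in the wild).
            tokens = line[54:].split()
            adtype = tokens[-1].upper() if tokens else ""
            element = _AUTODOCK_TYPE_TO_ELEMENT.get(adtype, adtype or "X").capitalize()
        else:
            element = _element_from_pdb_line(line)
        atoms.append(
            Atom(
                element=element or "X",
                coords=np.array([x, y, z]),
                residue_name=residue_name,
                residue_seq=residue_seq,
                chain_id=chain_id,
                is_hetero=line.startswith("HETATM"),
            )
        )
    return atoms


def _filter_receptor_atoms(
    atoms: Sequence[Atom], exclude_hetero_names: frozenset[str], strip_hetero: bool
) -> list[Atom]:
    # Hetero residues that look like chain members (MSE and friends: a
    # carbon scaffold of >= 4 heavy atoms, not a water or ion name) are
    # retained as polymer; free-standing hetero molecules are stripped.
    by_residue: dict[tuple[str, int, str], list[Atom]] = {}
    for a in atoms:
        by_residue.setdefault((a.chain_id, a.residue_seq, a.residue_name), []).append(a)
    polymer_het = {
        key
        for key, members in by_residue.items()
        if any(m.is_hetero for m in members)
        and key[2].upper() not in WATER_NAMES | ION_NAMES
        and key[2].upper() in {"MSE", "SEC", "PYL", "CSO", "PTR", "SEP", "TPO", "KCX", "LLP", "MLY", "HYP"}
        and sum(m.element.upper() == "C" for m in members) >= 2
    }
    kept: list[Atom] = []
    for a in atoms:
        if a.element.upper() in ("H", "D"):
            continue
        name = a.residue_name.upper()
        if name in WATER_NAMES or name in exclude_hetero_names:
            continue
        if a.is_hetero and name in ION_NAMES:
            continue
        if a.is_hetero and strip_hetero and (a.chain_id, a.residue_seq, a.residue_name) not in polymer_het:
            continue
        kept.append(a)
    return kept


def read_receptor(
    path: str | Path,
    format: str = "auto",
    *,
    strip_hetero: bool = True,
    exclude_hetero_names: Iterable[str] = (),
) -> ProteinStructure:
    """Read a receptor from PDB or PDBQT into a heavy-atom structure.

    Waters (HOH/WAT), monatomic ions, hydrogens and — unless
    ``strip_hetero=False`` — free-standing hetero small molecules are
    removed.  Hetero polymer residues embedded in a chain (MSE and
    friends, recognised by a carbon scaffold of at least four atoms) are
    kept and classified as ``OTH`` downstream.

    Raises
    ------
    StructureParseError
        If a record cannot be parsed (the message names the line).
    EmptyStructureError
        If nothing remains after filtering.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = _detect_format(path, format)
    if fmt not in ("pdb", "pdbqt"):
        raise StructureParseError(f"unsupported receptor format {fmt!r}")
    lines = path.read_text().splitlines()
    atoms = _parse_pdb_like_atoms(lines, pdbqt=(fmt == "pdbqt"), source=str(path))
    kept = _filter_receptor_atoms(
        atoms, frozenset(n.upper() for n in exclude_hetero_names), strip_hetero
    )
    if not kept:
        raise EmptyStructureError(f"{path}: no heavy protein atoms remain after filtering")
    return ProteinStructure(kept)


def write_receptor_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write a structure as fixed-width PDB ATOM records (coordinates to 1e-3 Å)."""
    with open(path, "w") as fh:
        for serial, a in enumerate(structure.atoms, start=1):
            name = a.element.upper()[:4]
            fh.write(
                f"{'HETATM' if a.is_hetero else 'ATOM  '}{serial:5d} {name:>4s} "
                f"{a.residue_name:>3s} {a.chain_id:1s}{a.residue_seq:4d}    "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {a.element.upper():>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Ligand pose reading
# ---------------------------------------------------------------------------


def _poses_from_rdkit_mols(mols: list, source: str) -> list[LigandPose]:
    from rdkit import Chem

    poses: list[LigandPose] = []
    reference: tuple[str, ...] | None = None
    ref_bonds: list[tuple[int, int, int]] | None = None
    for k, mol in enumerate(mols, start=1):
        if mol is None:
            raise StructureParseError(f"{source}: molecule block {k} failed to parse")
        mol = Chem.RemoveHs(mol, sanitize=False)
        conf = mol.GetConformer()
        atoms = []
        for atom in mol.GetAtoms():
            pos = conf.GetAtomPosition(atom.GetIdx())
            atoms.append(
                Atom(
                    element=atom.GetSymbol(),
                    coords=np.array([pos.x, pos.y, pos.z]),
                    residue_name="LIG",
                    residue_seq=1,
                    chain_id="L",
                    is_hetero=True,
                )
            )
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), max(1, int(b.GetBondTypeAsDouble())))
            for b in mol.GetBonds()
        ]
        elements = tuple(a.element for a in atoms)
        if reference is None:
            reference, ref_bonds = elements, bonds
        elif elements != reference:
            raise TopologyError(
                f"{source}: pose {k} has different atoms than pose 1 "
                f"({len(elements)} vs {len(reference)})"
            )
        score = None
        if mol.HasProp("score"):
            try:
                score = float(mol.GetProp("score"))
            except ValueError:
                score = None
        poses.append(LigandPose(atoms, bonds or list(ref_bonds or []), pose_id=str(k), source_score=score))
    return poses


def _read_sdf_poses(path: Path) -> list[LigandPose]:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mols = list(supplier)
    if not mols:
        raise EmptyStructureError(f"{path}: no molecules found")
    return _poses_from_rdkit_mols(mols, str(path))


def _read_mol2_poses(path: Path) -> list[LigandPose]:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    text = path.read_text()
    blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE") if b.strip()]
    if not blocks:
        raise EmptyStructureError(f"{path}: no TRIPOS molecule records")
    mols = [Chem.MolFromMol2Block(b, sanitize=False, removeHs=False) for b in blocks]
    return _poses_from_rdkit_mols(mols, str(path))


#: Single-bond covalent radii (Å) used for distance-based bond perception in
#: PDBQT ligands, which carry no connectivity.
_COVALENT_RADII = {
    "C": 0.77, "N": 0.70, "O": 0.66, "S": 1.04, "P": 1.10, "F": 0.64,
    "CL": 0.99, "BR": 1.14, "I": 1.33, "B": 0.85, "SI": 1.17,
}


def perceive_bonds(atoms: Sequence[Atom], tolerance: float = 0.45) -> list[tuple[int, int, int]]:
    """Infer single bonds from interatomic distances and covalent radii."""
    coords = np.array([a.coords for a in atoms])
    radii = np.array([_COVALENT_RADII.get(a.element.upper(), 0.77) for a in atoms])
    bonds = []
    for i in range(len(atoms)):
        d = np.linalg.norm(coords[i + 1 :] - coords[i], axis=1)
        cutoff = radii[i] + radii[i + 1 :] + tolerance
        for off in np.nonzero(d <= cutoff)[0]:
            bonds.append((i, int(i + 1 + off), 1))
    return bonds


def _read_pdbqt_poses(path: Path) -> list[LigandPose]:
    models: list[list[str]] = []
    scores: list[float | None] = []
    current: list[str] | None = None
    current_score: float | None = None
    any_model = False
    for line in path.read_text().splitlines():
        if line.startswith("MODEL"):
            any_model = True
            current = []
            current_score = None
        elif line.startswith("ENDMDL"):
            if current:
                models.append(current)
                scores.append(current_score)
            current = None
        elif line.startswith("REMARK VINA RESULT:"):
            try:
                current_score = float(line.split(":", 1)[1].split()[0])
            except (IndexError, ValueError):
                current_score = None
            if current is None and not any_model:
                current = []
        else:
            if current is None:
                if any_model:
                    continue
                current = []
            current.append(line)
    if current and any(l.startswith(("ATOM", "HETATM")) for l in current):
        models.append(current)
        scores.append(current_score)
    if not models:
        raise EmptyStructureError(f"{path}: no coordinate models found")

    poses: list[LigandPose] = []
    ref_elements: tuple[str, ...] | None = None
    ref_bonds: list[tuple[int, int, int]] | None = None
    for k, (model_lines, score) in enumerate(zip(models, scores), start=1):
        atoms = [
            a
            for a in _parse_pdb_like_atoms(model_lines, pdbqt=True, source=f"{path} model {k}")
            if a.element.upper() not in ("H", "D")
        ]
        if not atoms:
            raise EmptyStructureError(f"{path}: model {k} has no heavy atoms")
        elements = tuple(a.element for a in atoms)
        if ref_elements is None:
            ref_elements = elements
            ref_bonds = perceive_bonds(atoms)
        elif elements != ref_elements:
            raise TopologyError(f"{path}: model {k} atom list differs from model 1")
        poses.append(LigandPose(atoms, list(ref_bonds or []), pose_id=str(k), source_score=score))
    return poses


def read_ligand_poses(path: str | Path, format: str = "auto") -> list[LigandPose]:
    """Read an ordered pose set (one ligand topology) from SDF, MOL2 or PDBQT.

    One :class:`LigandPose` per conformer/model, file order preserved,
    pose ids "1".."N".  PDBQT ``REMARK VINA RESULT`` energies (and SDF
    ``score`` properties) populate ``source_score``.  PDBQT carries no
    bond block, so bonds are perceived from covalent radii there.

    Raises :class:`TopologyError` if models disagree on the atom list.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = _detect_format(path, format)
    if fmt == "sdf":
        return _read_sdf_poses(path)
    if fmt == "mol2":
        return _read_mol2_poses(path)
    if fmt == "pdbqt":
        return _read_pdbqt_poses(path)
    raise StructureParseError(f"unsupported ligand format {fmt!r}")


def write_poses_sdf(poses: Sequence[LigandPose], path: str | Path) -> None:
    """Write a pose set as a multi-record V2000 SDF (scores as a `score` tag)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for pose in poses:
            mol = Chem.RWMol()
            for a in pose.atoms:
                mol.AddAtom(Chem.Atom(a.element.capitalize()))
            for i, j, order in pose.bonds:
                mol.AddBond(i, j, Chem.BondType.values.get(order, Chem.BondType.SINGLE))
            conf = Chem.Conformer(len(pose.atoms))
            for idx, a in enumerate(pose.atoms):
                conf.SetAtomPosition(idx, Point3D(*a.coords))
            mol.AddConformer(conf)
            out = mol.GetMol()
            out.SetProp("_Name", pose.pose_id)
            if pose.source_score is not None:
                out.SetProp("score", f"{pose.source_score:.4f}")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    Chem.SanitizeMol(out, catchErrors=True)
                except Exception:
                    pass
            writer.write(out)
    finally:
        writer.close()
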