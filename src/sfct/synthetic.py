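"""Self-contained synthetic fixtures: toy pockets, decoy pose sets, pseudo scores.

Training the correction term requires, per native complex, a cloud of
docked decoy poses spanning roughly 0–10+ Å RMSD plus the crystal pose
at exactly 0 Å — about 90 engine poses per complex in the corpus this
emulates.  Nothing here runs a docking engine; decoys are produced by
rigid-body (and optionally torsional) perturbation of the native pose
with an analytically controlled displacement magnitude, and engine
scores are replaced by a tunable affine-plus-noise function of the true
RMSD.  That preserves the statistical structure the method needs —
labels spanning the range, scores partially (or not at all) correlated
with pose quality — while remaining fully deterministic per seed.

Geometry note: for a rotation by angle θ about an axis through the
centroid, the displacement RMSD is 2·sin(θ/2)·sqrt(mean |v⊥|²) with v⊥
the atom offsets perpendicular to the axis, and a subsequent translation
t adds in quadrature (the centroid is preserved, so cross terms vanish).
Decoy generation inverts these closed forms to hit a stratified grid of
target RMSDs exactly, instead of rejection-sampling perturbation sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import GenerationError
from .featurizer import DEFAULT_SCHEME, ShellScheme, featurize_complex, schema_id
from .model import TrainingSet
from .pose_metrics import symmetry_corrected_rmsd
from .structure_io import STANDARD_RESIDUES, Atom, LigandPose, ProteinStructure

# Ligand heavy-atom element palette: drug-like composition, carbon dominated.
_LIGAND_ELEMENTS = ("C", "N", "O", "S", "Cl", "F")
_LIGAND_ELEMENT_P = (0.68, 0.12, 0.12, 0.03, 0.03, 0.02)

_BOND_LENGTH = 1.5  # Å, generic heavy-atom single bond
_MIN_CLEARANCE = 1.5  # Å, minimum protein–ligand heavy-atom separation


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


# ---------------------------------------------------------------------------
# Toy complexes
# ---------------------------------------------------------------------------


def _random_ligand(rng: np.random.Generator, n_atoms: int) -> LigandPose:
    """Random connected tree-shaped ligand with ~1.5 Å bonds, centered at origin."""
    elements = list(rng.choice(_LIGAND_ELEMENTS, size=n_atoms, p=_LIGAND_ELEMENT_P))
    elements[0] = "C"
    coords = np.zeros((n_atoms, 3))
    bonds: list[tuple[int, int, int]] = []
    for i in range(1, n_atoms):
        parent = i - 1 if rng.random() < 0.7 else int(rng.integers(0, i))
        for _attempt in range(60):
            candidate = coords[parent] + _BOND_LENGTH * _unit(rng)
            others = np.delete(coords[:i], parent, axis=0)
            if others.size == 0 or np.linalg.norm(others - candidate, axis=1).min() >= 1.2:
                break
        coords[i] = candidate
        bonds.append((parent, i, 1))
    coords -= coords.mean(axis=0)
    atoms = [
        Atom(el, c, residue_name="LIG", residue_seq=1, chain_id="L", is_hetero=True)
        for el, c in zip(elements, coords)
    ]
    return LigandPose(atoms, bonds, pose_id="native")


_RESIDUE_SIDE_ATOMS = {  # crude heavy-atom side-chain sizes per residue type
    "GLY": 0, "ALA": 1, "SER": 2, "CYS": 2, "THR": 3, "VAL": 3, "PRO": 3,
    "ASP": 4, "ASN": 4, "LEU": 4, "ILE": 4, "MET": 4, "GLU": 5, "GLN": 5,
    "LYS": 5, "HIS": 6, "ARG": 7, "PHE": 7, "TYR": 8, "TRP": 10,
}


def _build_residue(
    rng: np.random.Generator,
    name: str,
    seq: int,
    anchor: np.ndarray,
    outward: np.ndarray,
    gap: float,
) -> list[Atom]:
    """One residue whose CA sits ``gap`` Å beyond ``anchor`` along ``outward``."""
    ca = anchor + gap * outward
    positions = {"CA": ca}
    positions["N"] = ca + 1.46 * _unit(rng)
    positions["C"] = ca + 1.53 * _unit(rng)
    positions["O"] = positions["C"] + 1.23 * _unit(rng)
    side_elements = []
    prev = ca
    for k in range(_RESIDUE_SIDE_ATOMS.get(name, 3)):
        direction = 0.6 * outward + _unit(rng)
        prev = prev + _BOND_LENGTH * direction / np.linalg.norm(direction)
        element = "C"
        if k >= 1 and rng.random() < 0.25:
            element = "N" if rng.random() < 0.5 else "O"
        if name in ("CYS", "MET") and k == 1:
            element = "S"
        side_elements.append((element, prev))
    atoms = [
        Atom("N", positions["N"], name, seq, "A"),
        Atom("C", positions["CA"], name, seq, "A"),
        Atom("C", positions["C"], name, seq, "A"),
        Atom("O", positions["O"], name, seq, "A"),
    ]
    atoms.extend(Atom(el, pos, name, seq, "A") for el, pos in side_elements)
    return atoms


def generate_toy_complex(
    seed: int,
    n_residues: int = 20,
    n_ligand_atoms: int = 15,
    max_retries: int = 25,
) -> tuple[ProteinStructure, LigandPose]:
    """Deterministic toy binding pocket: residues arranged around a buried ligand.

    Pocket residues anchor to randomly chosen ligand atoms at 3–6.5 Å
    gaps, so the native pose always has short-range contacts; the whole
    construction guarantees >= 1.5 Å protein–ligand clearance.  Sizes of
    5–50 residues and 5–40 ligand atoms are supported.
    """
    if not (5 <= n_residues <= 50):
        raise GenerationError(f"n_residues must be in [5, 50], got {n_residues}")
    if not (5 <= n_ligand_atoms <= 40):
        raise GenerationError(f"n_ligand_atoms must be in [5, 40], got {n_ligand_atoms}")
    rng = np.random.default_rng(seed)
    ligand = _random_ligand(rng, n_ligand_atoms)
    lig_coords = ligand.coords

    atoms: list[Atom] = []
    for i in range(n_residues):
        name = str(rng.choice(STANDARD_RESIDUES))
        anchor_idx = int(rng.integers(0, n_ligand_atoms))
        anchor = lig_coords[anchor_idx]
        radial = anchor + 0.35 * _unit(rng)
        norm = np.linalg.norm(radial)
        outward = radial / norm if norm > 1e-9 else _unit(rng)
        gap = float(rng.uniform(3.0, 6.5))
        for _attempt in range(max_retries):
            residue = _build_residue(rng, name, i + 1, anchor, outward, gap)
            res_coords = np.array([a.coords for a in residue])
            dmin = np.linalg.norm(
                res_coords[:, None, :] - lig_coords[None, :, :], axis=2
            ).min()
            if dmin >= _MIN_CLEARANCE:
                atoms.extend(residue)
                break
            gap += 0.5
        else:
            raise GenerationError(
                f"could not place residue {i + 1} without clashes after {max_retries} tries"
            )
    return ProteinStructure(atoms), ligand


# ---------------------------------------------------------------------------
# Decoy poses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecoySpec:
    """Controls the decoy pose cloud generated around one native pose.

    ``n_decoys_per_native`` defaults to 90, the per-complex engine pose
    count the corpus emulates.  Target displacements are stratified
    uniformly over ``rmsd_range`` with ``translation_sd`` jitter; if
    ``torsion_sd`` > 0, torsions about acyclic single bonds are perturbed
    before the rigid move.
    """

    n_decoys_per_native: int = 90
    rmsd_range: tuple[float, float] = (0.2, 12.0)
    translation_sd: float = 0.3
    torsion_sd: float = 0.0  # degrees
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rmsd_range
        if not (0 <= lo < hi):
            raise ValueError(f"rmsd_range must satisfy 0 <= lo < hi, got {self.rmsd_range}")
        if self.n_decoys_per_native < 1:
            raise ValueError("n_decoys_per_native must be >= 1")


def _rotatable_bonds(pose: LigandPose) -> list[tuple[int, int]]:
    """Acyclic single bonds with at least one heavy atom on each side."""
    import networkx as nx

    g = nx.Graph((i, j) for i, j, _ in pose.bonds)
    bridges = set(frozenset(b) for b in nx.bridges(g)) if g.number_of_edges() else set()
    rotatable = []
    for i, j, order in pose.bonds:
        if order != 1 or frozenset((i, j)) not in bridges:
            continue
        if g.degree[i] > 1 and g.degree[j] > 1:
            rotatable.append((i, j))
    return rotatable


def _apply_torsions(pose: LigandPose, rng: np.random.Generator, sd_degrees: float) -> np.ndarray:
    import networkx as nx

    coords = pose.coords.copy()
    g = nx.Graph((i, j) for i, j, _ in pose.bonds)
    for i, j in _rotatable_bonds(pose):
        g.remove_edge(i, j)
        moving = nx.node_connected_component(g, j)
        g.add_edge(i, j)
        axis = coords[j] - coords[i]
        if np.linalg.norm(axis) < 1e-9:
            continue
        angle = np.deg2rad(rng.normal(0.0, sd_degrees))
        rot = _rotation_matrix(axis, angle)
        idx = sorted(moving - {j})
        if idx:
            coords[idx] = (coords[idx] - coords[j]) @ rot.T + coords[j]
    return coords


def _rigid_perturb_to_target(
    coords: np.ndarray, target: float, rng: np.random.Generator
) -> np.ndarray:
    """Rotate about the centroid then translate so the displacement RMSD is ``target``."""
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    axis = _unit(rng)
    perp_sq = np.mean(
        np.sum(centered**2, axis=1) - (centered @ axis) ** 2
    )
    rmsd_rot_max = 2.0 * np.sqrt(max(perp_sq, 0.0))
    rot_target = min(rng.uniform(0.2, 0.6) * target, 0.95 * rmsd_rot_max)
    if rmsd_rot_max > 1e-9 and rot_target > 0:
        angle = 2.0 * np.arcsin(min(rot_target / rmsd_rot_max, 1.0))
        rotated = centered @ _rotation_matrix(axis, angle).T
        achieved_rot = float(np.sqrt(np.mean(np.sum((rotated - centered) ** 2, axis=1))))
    else:
        rotated = centered
        achieved_rot = 0.0
    remaining = np.sqrt(max(target**2 - achieved_rot**2, 0.0))
    return rotated + centroid + remaining * _unit(rng)


def generate_decoys(
    native: LigandPose, spec: DecoySpec = DecoySpec()
) -> tuple[list[LigandPose], np.ndarray]:
    """Perturbed copies of the native pose with recomputed symmetry-corrected labels.

    Targets are stratified over ``spec.rmsd_range`` so the label spectrum
    covers the whole range (at defaults, well over 10% of decoys fall
    below 2 Å and above 8 Å).  Every returned label is the
    symmetry-corrected RMSD recomputed from the decoy coordinates, not
    the target, so labels are exact by construction.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.rmsd_range
    n = spec.n_decoys_per_native
    strata = lo + (hi - lo) * (np.arange(n) + rng.uniform(0, 1, size=n)) / n
    targets = np.abs(strata + rng.normal(0.0, spec.translation_sd, size=n))
    rng.shuffle(targets)

    poses: list[LigandPose] = []
    labels = np.empty(n)
    for k, target in enumerate(targets):
        coords = native.coords
        if spec.torsion_sd > 0:
            coords = _apply_torsions(native, rng, spec.torsion_sd)
            residual_sq = np.mean(np.sum((coords - native.coords) ** 2, axis=1))
            target = float(np.sqrt(max(target**2 - residual_sq, 0.0)))
        coords = _rigid_perturb_to_target(coords, float(target), rng)
        decoy = native.with_coords(coords, pose_id=f"decoy_{k + 1:03d}")
        labels[k] = symmetry_corrected_rmsd(decoy, native).symmetry_rmsd
        poses.append(decoy)
    return poses, labels


# ---------------------------------------------------------------------------
# Pseudo docking scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PseudoScoreSpec:
    """Affine-plus-noise stand-in for an engine score.

    P = base_affinity + rmsd_coupling·RMSD + N(0, noise_sd).  The
    defaults (-9 kcal/mol base, 0.4 kcal/mol/Å coupling, 1.0 kcal/mol
    noise) give scores in a Vina-like range that are informative but
    imperfect; set ``rmsd_coupling=0`` for the hard case where the
    docking score carries no pose-quality signal at all.
    """

    base_affinity: float = -9.0
    rmsd_coupling: float = 0.4
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def pseudo_docking_score(
    true_rmsd: float | np.ndarray,
    spec: PseudoScoreSpec = PseudoScoreSpec(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Seeded pseudo-score for one or many poses given their true RMSDs."""
    rmsd = np.atleast_1d(np.asarray(true_rmsd, dtype=float))
    if np.any(rmsd < 0):
        raise ValueError("true_rmsd must be non-negative")
    rng = rng or np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=rmsd.shape) if spec.noise_sd > 0 else 0.0
    return spec.base_affinity + spec.rmsd_coupling * rmsd + noise


# ---------------------------------------------------------------------------
# Assembled corpora
# ---------------------------------------------------------------------------


@dataclass
class ComplexRecord:
    """One native complex with its decoy poses, labels and pseudo scores."""

    complex_id: str
    protein: ProteinStructure
    native: LigandPose
    decoys: list[LigandPose]
    labels: np.ndarray  # symmetry-corrected RMSD per decoy, Å
    scores: np.ndarray | None = None  # pseudo docking score per decoy


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def generate_complex_set(
    seed: int,
    n_complexes: int,
    n_decoys_per_native: int = 20,
    rmsd_range: tuple[float, float] = (0.2, 12.0),
    score_spec: PseudoScoreSpec | None = None,
    residue_range: tuple[int, int] = (12, 28),
    ligand_atom_range: tuple[int, int] = (8, 25),
) -> list[ComplexRecord]:
    """A set of toy complexes, each with a stratified decoy cloud and optional scores."""
    seeds = _child_seeds(seed, n_complexes * 3).reshape(n_complexes, 3)
    records = []
    for i, (cseed, dseed, sseed) in enumerate(seeds):
        size_rng = np.random.default_rng(cseed)
        protein, native = generate_toy_complex(
            int(cseed),
            n_residues=int(size_rng.integers(*residue_range)),
            n_ligand_atoms=int(size_rng.integers(*ligand_atom_range)),
        )
        decoys, labels = generate_decoys(
            native,
            DecoySpec(
                n_decoys_per_native=n_decoys_per_native,
                rmsd_range=rmsd_range,
                seed=int(dseed),
            ),
        )
        scores = None
        if score_spec is not None:
            scores = pseudo_docking_score(
                labels, score_spec, rng=np.random.default_rng(int(sseed))
            )
        records.append(
            ComplexRecord(f"cplx_{i + 1:04d}", protein, native, decoys, labels, scores)
        )
    return records


def build_training_set(
    records: Sequence[ComplexRecord],
    scheme: ShellScheme = DEFAULT_SCHEME,
    include_native: bool = True,
) -> TrainingSet:
    """Featurize a complex set into a model-ready training set.

    Each native (crystal) pose enters with label exactly 0 Å alongside
    its decoys; grouping is by complex so splits can avoid pose leakage.
    """
    features, labels, groups = [], [], []
    for rec in records:
        poses = ([rec.native] if include_native else []) + list(rec.decoys)
        pose_labels = ([0.0] if include_native else []) + list(rec.labels)
        for pose, label in zip(poses, pose_labels):
            features.append(featurize_complex(rec.protein, pose, scheme).counts)
            labels.append(label)
            groups.append(rec.complex_id)
    return TrainingSet(
        features=np.array(features),
        labels=np.array(labels),
        group_id=np.array(groups),
        schema_id=schema_id(scheme),
    )


# ---------------------------------------------------------------------------
# Screening libraries
# ---------------------------------------------------------------------------


@dataclass
class ScreeningLibrary:
    """A toy receptor with per-ligand docked pose sets and active/decoy labels."""

    protein: ProteinStructure
    ligand_ids: list[str]
    is_active: np.ndarray
    poses: list[list[LigandPose]]  # per ligand, engine output order
    pose_scores: list[np.ndarray]  # pseudo engine score per pose
    best_true_displacement: np.ndarray  # Å, per ligand
    pocket_center: np.ndarray = field(default_factory=lambda: np.zeros(3))


def simulate_screening_library(
    n_actives: int,
    n_decoy_ligands: int,
    spec: PseudoScoreSpec = PseudoScoreSpec(),
    seed: int = 0,
    n_poses_per_ligand: int = 5,
    active_displacement: tuple[float, float] = (0.3, 2.0),
    decoy_displacement: tuple[float, float] = (4.0, 10.0),
) -> ScreeningLibrary:
    """Active/decoy ligand library docked into one shared toy pocket.

    Actives receive pose sets that sit snugly in the pocket (small
    displacement from their in-pocket placement, hence strong short-shell
    contacts and favourable pseudo-scores); decoy ligands receive poses
    pushed to the pocket periphery.  Deterministic per seed.
    """
    if n_actives < 1 or n_decoy_ligands < 1:
        raise GenerationError("need at least one active and one decoy ligand")
    rng = np.random.default_rng(seed)
    protein, reference = generate_toy_complex(
        int(rng.integers(0, 2**31 - 1)), n_residues=20, n_ligand_atoms=15
    )
    n_total = n_actives + n_decoy_ligands
    is_active = np.array([True] * n_actives + [False] * n_decoy_ligands)

    ligand_ids, all_poses, all_scores, best_disp = [], [], [], np.empty(n_total)
    for i in range(n_total):
        active = bool(is_active[i])
        ligand = _random_ligand(rng, int(rng.integers(8, 20)))
        lo, hi = active_displacement if active else decoy_displacement
        displacements = np.sort(rng.uniform(lo, hi, size=n_poses_per_ligand))
        poses = []
        for k, disp in enumerate(displacements):
            coords = _rigid_perturb_to_target(ligand.coords, float(disp), rng)
            poses.append(ligand.with_coords(coords, pose_id=f"pose_{k + 1}"))
        scores = pseudo_docking_score(displacements, spec, rng=rng)
        ligand_ids.append(f"{'act' if active else 'dec'}_{i + 1:04d}")
        all_poses.append(poses)
        all_scores.append(scores)
        best_disp[i] = displacements[0]
    return ScreeningLibrary(
        protein, ligand_ids, is_active, all_poses, all_scores, best_disp
    )
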