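"""Heavy-atom ligand RMSD in the receptor frame, with graph-symmetry correction.

Docking RMSD is computed without superposition: both poses live in the
common receptor coordinate frame, so translation errors count.  The
symmetry-corrected variant minimises the RMSD over all element- and
adjacency-preserving automorphisms of the ligand's bond graph, the same
convention as Open Babel's ``obrms``: a benzene ring rotated by 60° in
place is 0 Å from itself even though the naive atom-order RMSD is not.
Bond orders are ignored when matching — a C6 ring rotation maps formal
single bonds onto double bonds yet is chemically the same pose, and
order-sensitive matching would miss it.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .exceptions import TopologyError
from .structure_io import LigandPose

#: Automorphism enumeration cap; past this the identity mapping is used.
DEFAULT_AUTOMORPHISM_CAP = 10_000


@dataclass(frozen=True)
class RmsdResult:
    """Naive and symmetry-corrected RMSD plus the minimising atom mapping."""

    naive_rmsd: float
    symmetry_rmsd: float
    mapping: tuple[int, ...]
    capped: bool = False  # True if enumeration hit the cap and fell back to identity


def heavy_atom_rmsd(pose_a: LigandPose, pose_b: LigandPose) -> float:
    """RMSD over matched heavy atoms, no superposition.

    Requires identical atom count and ordering.
    """
    if len(pose_a) != len(pose_b):
        raise TopologyError(
            f"atom count mismatch: {len(pose_a)} vs {len(pose_b)}"
        )
    delta = pose_a.coords - pose_b.coords
    return float(np.sqrt(np.mean(np.sum(delta * delta, axis=1))))


def _ligand_graph(pose: LigandPose) -> nx.Graph:
    g = nx.Graph()
    for i, atom in enumerate(pose.atoms):
        g.add_node(i, element=atom.element.upper())
    for i, j, _order in pose.bonds:
        g.add_edge(i, j)
    return g


def _same_topology(pose_a: LigandPose, pose_b: LigandPose) -> bool:
    if pose_a.elements != pose_b.elements:
        return False
    edges_a = {frozenset((i, j)) for i, j, _ in pose_a.bonds}
    edges_b = {frozenset((i, j)) for i, j, _ in pose_b.bonds}
    return edges_a == edges_b


def ligand_automorphisms(pose: LigandPose, cap: int = DEFAULT_AUTOMORPHISM_CAP):
    """Yield element-preserving bond-graph automorphisms as index permutations.

    Enumeration stops after ``cap`` mappings; the caller decides how to
    handle truncation.
    """
    g = _ligand_graph(pose)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g, node_match=lambda a, b: a["element"] == b["element"]
    )
    for count, mapping in enumerate(matcher.isomorphisms_iter()):
        if count >= cap:
            return
        yield tuple(mapping[i] for i in range(len(pose)))


def symmetry_corrected_rmsd(
    pose_a: LigandPose,
    pose_b: LigandPose,
    cap: int = DEFAULT_AUTOMORPHISM_CAP,
) -> RmsdResult:
    """Minimum RMSD over ligand bond-graph automorphisms.

    Both poses must share one molecular graph (same element sequence and
    bond set).  If the number of automorphisms exceeds ``cap`` the result
    falls back to the identity mapping and sets ``capped``.
    """
    if not _same_topology(pose_a, pose_b):
        raise TopologyError("poses do not share a molecular graph (elements + bonds)")
    coords_a = pose_a.coords
    coords_b = pose_b.coords
    naive = heavy_atom_rmsd(pose_a, pose_b)

    best = naive
    best_mapping = tuple(range(len(pose_a)))
    n_seen = 0
    exhausted = True
    for perm in ligand_automorphisms(pose_a, cap=cap):
        n_seen += 1
        delta = coords_a - coords_b[list(perm)]
        rmsd = float(np.sqrt(np.mean(np.sum(delta * delta, axis=1))))
        if rmsd < best:
            best = rmsd
            best_mapping = perm
    if n_seen >= cap:
        # Enumeration truncated: report the identity result honestly.
        return RmsdResult(naive, naive, tuple(range(len(pose_a))), capped=True)
    return RmsdResult(naive, best, best_mapping, capped=False)
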