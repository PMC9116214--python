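"""Hybrid rescoring: combine a docking score with the predicted-RMSD correction.

The hybrid score of a pose is the linear combination

    E = alpha * P + beta * S

where P is any docking engine's score (kcal/mol-like, lower is better)
and S is the model's predicted RMSD in Å.  Although the units differ,
S behaves like a pseudo-free-energy: it is zero only in the native-like
state and grows as the pose deviates, so adding it penalises poses that
look non-native regardless of how favourable the engine scored them.
The default weights alpha = beta = 0.5 were tuned for the AutoDock Vina
score; other engines' scores can be plugged in unchanged but the weights
are not re-optimised for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ScoringError
from .featurizer import DEFAULT_SCHEME, ShellScheme, featurize_complex
from .model import SFCTModel, predict_sfct
from .structure_io import LigandPose, ProteinStructure


@dataclass(frozen=True)
class HybridWeights:
    """Weights (alpha on the docking score, beta on the correction term).

    The defaults were calibrated for the Vina score only; with other
    engines they are used as-is.
    """

    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValueError("weights must be finite")


DEFAULT_WEIGHTS = HybridWeights()

#: Engines emit at most this many poses per ligand for screening; the
#: ligand-level score is the best hybrid score among the first 20 poses.
SCREENING_POSE_CAP = 20


@dataclass(frozen=True)
class ScoredPose:
    """One pose's docking score P, correction S and hybrid score E (all lower = better)."""

    pose_id: str
    P: float
    S: float
    E: float
    input_index: int = 0


def hybrid_score(P: float, S: float, weights: HybridWeights = DEFAULT_WEIGHTS) -> float:
    """E = alpha·P + beta·S.  Inputs must be finite; S is an RMSD, so >= 0."""
    if not (math.isfinite(P) and math.isfinite(S)):
        raise ScoringError(f"non-finite score inputs P={P}, S={S}")
    return weights.alpha * P + weights.beta * S


def rescore_poses(
    model: SFCTModel | None,
    protein: ProteinStructure,
    poses: Sequence[LigandPose],
    scores: Mapping[str, float] | Sequence[float] | None = None,
    weights: HybridWeights = DEFAULT_WEIGHTS,
    scheme: ShellScheme = DEFAULT_SCHEME,
) -> list[ScoredPose]:
    """Featurize, predict S, combine with P and return poses sorted by E.

    ``scores`` maps pose_id to the engine score (or lists them in pose
    order); poses without a score fall back to their embedded
    ``source_score``.  A missing score is an error unless alpha = 0; a
    model is required unless beta = 0.  The sort ascending by E breaks
    ties by lower P and then by input order, so output is deterministic.
    """
    P_values: list[float] = []
    for idx, pose in enumerate(poses):
        P = None
        if scores is not None:
            P = scores.get(pose.pose_id) if isinstance(scores, Mapping) else scores[idx]
        if P is None:
            P = pose.source_score
        if P is None:
            if weights.alpha != 0.0:
                raise ScoringError(f"pose {pose.pose_id!r} has no docking score and alpha != 0")
            P = 0.0
        if not math.isfinite(P):
            raise ScoringError(f"pose {pose.pose_id!r} has non-finite docking score {P}")
        P_values.append(float(P))

    if weights.beta != 0.0:
        if model is None:
            raise ScoringError("a fitted model is required when beta != 0")
        vectors = [featurize_complex(protein, pose, scheme) for pose in poses]
        S_values = predict_sfct(model, vectors)
    else:
        S_values = np.zeros(len(poses))

    scored = [
        ScoredPose(
            pose_id=pose.pose_id,
            P=P,
            S=float(S),
            E=hybrid_score(P, float(S), weights),
            input_index=idx,
        )
        for idx, (pose, P, S) in enumerate(zip(poses, P_values, S_values))
    ]
    return sorted(scored, key=lambda sp: (sp.E, sp.P, sp.input_index))


def ligand_screening_score(
    scored: Sequence[ScoredPose], pose_cap: int = SCREENING_POSE_CAP
) -> float:
    """Ligand-level screening score: best (minimum) E among the first ``pose_cap`` poses.

    The cap is applied in the engine's output order (engines emit
    best-first), not in rescored order.
    """
    if not scored:
        raise ScoringError("ligand has no scored poses")
    in_input_order = sorted(scored, key=lambda sp: sp.input_index)[:pose_cap]
    return min(sp.E for sp in in_input_order)


def rank_proteins_reverse(
    per_protein: Mapping[str, Sequence[float]],
) -> list[tuple[str, float]]:
    """Rank proteins for reverse screening: best pocket score per protein, ascending.

    A protein's binding strength to the query ligand is the lowest hybrid
    (or engine) score over all its candidate pockets; ties order
    lexicographically by protein id.
    """
    if not per_protein:
        raise ScoringError("no proteins to rank")
    ranking = []
    for protein_id, pocket_scores in per_protein.items():
        if len(pocket_scores) == 0:
            raise ScoringError(f"protein {protein_id!r} has no pocket scores")
        ranking.append((protein_id, float(min(pocket_scores))))
    return sorted(ranking, key=lambda item: (item[1], item[0]))
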