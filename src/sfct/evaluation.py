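"""Docking and screening evaluation metrics.

Pose-ranking quality is summarised by the top-N success rate (fraction
of complexes whose best-ranked N poses contain one within 2 Å of the
native pose) and the mean RMSD of the top-ranked pose.  Screening
quality over an active/decoy library uses the enrichment factor at a
fraction of the ranked database and the ROC-AUC, with all scores
oriented lower-is-better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .exceptions import MetricError


@dataclass(frozen=True)
class DockingCase:
    """One complex's pose RMSDs (Å) in the order a scoring method ranked them."""

    case_id: str
    ranked_rmsds: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ranked_rmsds:
            raise MetricError(f"case {self.case_id!r} has no poses")
        if any(r < 0 or not math.isfinite(r) for r in self.ranked_rmsds):
            raise MetricError(f"case {self.case_id!r} has invalid RMSD values")


@dataclass
class ScreeningSet:
    """Per-ligand screening scores (lower = better) with active/decoy labels."""

    scores: np.ndarray
    is_active: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.is_active = np.asarray(self.is_active, dtype=bool)
        if len(self.scores) != len(self.is_active):
            raise MetricError("scores and labels lengths disagree")

    def __len__(self) -> int:
        return len(self.scores)


def success_rate(
    cases: Sequence[DockingCase], top_n: int = 1, cutoff: float = 2.0
) -> float:
    """Fraction of cases with a pose within ``cutoff`` Å among the top ``top_n``.

    The boundary is inclusive (RMSD == cutoff counts as success), the
    CASF convention.  Monotone non-decreasing in both top_n and cutoff.
    """
    if not cases:
        raise MetricError("no docking cases")
    if top_n < 1:
        raise MetricError("top_n must be >= 1")
    hits = sum(1 for c in cases if min(c.ranked_rmsds[:top_n]) <= cutoff)
    return hits / len(cases)


def average_topk_rmsd(cases: Sequence[DockingCase], k: int = 1) -> float:
    """Mean over cases of the best RMSD among each case's top ``k`` ranked poses.

    With k=1 this is the mean RMSD of the top-ranked pose — lower means
    the scoring method ranks near-native poses first.
    """
    if not cases:
        raise MetricError("no docking cases")
    for c in cases:
        if len(c.ranked_rmsds) < k:
            raise MetricError(f"case {c.case_id!r} has fewer than {k} poses")
    return float(np.mean([min(c.ranked_rmsds[:k]) for c in cases]))


def enrichment_factor(screening_set: ScreeningSet, fraction: float = 0.01) -> float:
    """Active concentration in the top ``fraction`` of the ranking over the base rate.

    EF = (actives in top bucket / bucket size) / (total actives / N) with
    bucket size ceil(fraction·N); ranking ascends by score with stable
    input-order tie-breaking.  EF is 0 when no active makes the bucket
    and at most min(N/bucket, N/actives).
    """
    if not 0 < fraction <= 1:
        raise MetricError(f"fraction must be in (0, 1], got {fraction}")
    n = len(screening_set)
    n_actives = int(screening_set.is_active.sum())
    if n == 0 or n_actives == 0:
        raise MetricError("enrichment factor undefined without actives")
    bucket = math.ceil(fraction * n)
    order = np.argsort(screening_set.scores, kind="stable")
    hits = int(screening_set.is_active[order[:bucket]].sum())
    return (hits / bucket) / (n_actives / n)


def roc_auc(screening_set: ScreeningSet) -> float:
    """Probability a random active outscores (scores lower than) a random decoy.

    Ties count one half (Mann–Whitney convention); requires both classes.
    """
    labels = screening_set.is_active
    if labels.all() or not labels.any():
        raise MetricError("ROC-AUC requires both actives and decoys")
    # Lower score = better, so rank on the negated scores.
    return float(roc_auc_score(labels.astype(int), -screening_set.scores))
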