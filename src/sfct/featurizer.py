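"""Multi-shell residue–atom contact featurization.

A protein–ligand pose is summarised as integer contact counts over
concentric distance shells: every (protein heavy atom, ligand heavy
atom) pair whose Euclidean distance falls inside shell *k* increments
the bin (residue class of the protein atom, element class of the ligand
atom, k).  The default scheme uses 14 shells of width 1.5 Å starting at
0 Å, so the census covers all pairs closer than 21 Å and the vector has
21 residue classes × 7 element classes × 14 shells = 2058 bins.

The count vector is origin-free (rigid motions of the whole complex
leave it unchanged) but sensitive to how the ligand sits in the pocket,
which is what makes it predictive of pose RMSD.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .exceptions import EmptyStructureError
from .structure_io import (
    ELEMENT_CLASSES,
    RESIDUE_CLASSES,
    LigandPose,
    ProteinStructure,
    element_class_index,
)


@dataclass(frozen=True)
class ShellScheme:
    """Concentric-shell binning: ``n_shells`` half-open bins of ``shell_width`` Å."""

    n_shells: int = 14
    shell_width: float = 1.5
    origin: float = 0.0

    def __post_init__(self) -> None:
        if self.n_shells < 1:
            raise ValueError("n_shells must be >= 1")
        if self.shell_width <= 0:
            raise ValueError("shell_width must be positive")

    @property
    def max_distance(self) -> float:
        """Upper edge of the outermost shell, Å (exclusive)."""
        return self.origin + self.n_shells * self.shell_width


DEFAULT_SCHEME = ShellScheme()


def schema_id(scheme: ShellScheme) -> str:
    """Stable hash of (alphabets, scheme, bin ordering) identifying a feature layout."""
    payload = repr((RESIDUE_CLASSES, ELEMENT_CLASSES, scheme.n_shells, scheme.shell_width,
                    scheme.origin, "residue-major,element,shell"))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-order contact counts for one pose plus the schema they follow."""

    counts: np.ndarray  # int64, length n_residue_classes * n_element_classes * n_shells
    schema_id: str

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or np.any(counts < 0):
            raise ValueError("counts must be a 1-D non-negative integer vector")
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return len(self.counts)


def shell_index(distance: float, scheme: ShellScheme = DEFAULT_SCHEME) -> int | None:
    """1-based shell for a distance, or None beyond the outermost shell.

    Shell k covers [origin + (k-1)·width, origin + k·width).
    """
    if distance < 0:
        raise ValueError(f"distance must be non-negative, got {distance}")
    if distance < scheme.origin or distance >= scheme.max_distance:
        return None
    return int((distance - scheme.origin) // scheme.shell_width) + 1


def feature_schema(scheme: ShellScheme = DEFAULT_SCHEME) -> list[tuple[str, str, int]]:
    """Ordered bin labels (residue_class, element_class, shell).

    Residue classes run alphabetically with OTH last, element classes in
    (C, N, O, S, P, HAL, OTH), shells ascending; residue-major order.
    """
    return [
        (res, elem, shell)
        for res in RESIDUE_CLASSES
        for elem in ELEMENT_CLASSES
        for shell in range(1, scheme.n_shells + 1)
    ]


def featurize_complex(
    protein: ProteinStructure,
    pose: LigandPose,
    scheme: ShellScheme = DEFAULT_SCHEME,
) -> FeatureVector:
    """Count protein–ligand heavy-atom pairs per (residue class, element class, shell).

    The sum of the returned counts equals the number of atom pairs closer
    than ``scheme.max_distance``.
    """
    if len(protein) == 0 or len(pose) == 0:
        raise EmptyStructureError("featurization requires non-empty protein and ligand")
    n_res, n_elem, n_shell = len(RESIDUE_CLASSES), len(ELEMENT_CLASSES), scheme.n_shells

    dists = cdist(protein.coords, pose.coords)
    shells = np.floor((dists - scheme.origin) / scheme.shell_width).astype(np.int64)
    valid = (dists >= scheme.origin) & (shells >= 0) & (shells < n_shell)

    res_idx = protein.residue_class_indices  # (N,)
    elem_idx = np.array([element_class_index(a.element) for a in pose.atoms], dtype=np.intp)
    flat = (
        res_idx[:, None] * (n_elem * n_shell)
        + elem_idx[None, :] * n_shell
        + shells
    )
    counts = np.bincount(flat[valid].ravel(), minlength=n_res * n_elem * n_shell)
    return FeatureVector(counts.astype(np.int64), schema_id(scheme))


def features_to_frame(
    vectors: Sequence[FeatureVector],
    pose_ids: Sequence[str] | None = None,
    labels: Sequence[float] | None = None,
    scheme: ShellScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame (one row per pose, bins as columns).

    Columns are named ``RES:ELEM:SHELL``; an optional ``label`` column
    carries pose RMSDs for training.
    """
    sid = schema_id(scheme)
    for v in vectors:
        if v.schema_id != sid:
            raise ValueError("feature vector schema does not match the given scheme")
    columns = [f"{r}:{e}:{s}" for r, e, s in feature_schema(scheme)]
    data = np.vstack([v.counts for v in vectors]) if vectors else np.empty((0, len(columns)), dtype=np.int64)
    frame = pd.DataFrame(data, columns=columns)
    frame.insert(0, "pose_id", list(pose_ids) if pose_ids is not None else [str(i + 1) for i in range(len(vectors))])
    if labels is not None:
        frame["label"] = np.asarray(labels, dtype=float)
    return frame
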