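"""The scoring-function correction term: a boosted-forest pose-RMSD regressor.

The correction term S is the RMSD (Å, vs. the native pose) that a model
predicts from a pose's contact-shell feature vector.  Training uses
AdaBoost.R2 with random-forest base estimators: 10 boosting rounds, each
round a 50-tree forest with max_features=512, max_depth=50 and
out-of-bag scoring.  Poses with label > 10 Å are excluded before
training — such poses sit far outside the binding site and only add
noise to the regression target.

Crystal (native) poses carry label exactly 0 Å, anchoring the low end of
the target range; predictions are clamped at 0 since RMSD cannot be
negative while a boosted ensemble can extrapolate below it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostRegressor, RandomForestRegressor

from .exceptions import ModelFormatError, ModelStateError, SchemaError, TrainingError
from .featurizer import DEFAULT_SCHEME, FeatureVector, ShellScheme, feature_schema, schema_id

logger = logging.getLogger(__name__)

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SFCTHyperparams:
    """Hyperparameters of the boosted-forest RMSD regressor."""

    n_boost_rounds: int = 10
    trees_per_forest: int = 50
    max_features: int = 512
    max_depth: int = 50
    use_oob: bool = True
    boosting_loss: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_boost_rounds", "trees_per_forest", "max_features", "max_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.boosting_loss not in ("linear", "square", "exponential"):
            raise ValueError(f"unknown boosting loss {self.boosting_loss!r}")


@dataclass
class TrainingSet:
    """Feature matrix, RMSD labels (Å) and per-pose native-complex groups."""

    features: np.ndarray  # (n_poses, n_bins)
    labels: np.ndarray  # (n_poses,), Å
    group_id: np.ndarray  # (n_poses,), native-complex identifier
    schema_id: str

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        self.labels = np.asarray(self.labels, dtype=float)
        self.group_id = np.asarray(self.group_id)
        if not (len(self.features) == len(self.labels) == len(self.group_id)):
            raise TrainingError("features, labels and group_id lengths disagree")
        if np.any(self.labels < 0):
            raise TrainingError("RMSD labels must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)


def training_set_from_frame(frame: pd.DataFrame, scheme: ShellScheme = DEFAULT_SCHEME) -> TrainingSet:
    """Build a TrainingSet from a feature frame with pose_id/label (and optional group) columns."""
    columns = [f"{r}:{e}:{s}" for r, e, s in feature_schema(scheme)]
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"feature frame lacks {len(missing)} schema columns (first: {missing[0]})")
    if "label" not in frame.columns:
        raise TrainingError("feature frame has no 'label' column")
    groups = frame["group"] if "group" in frame.columns else frame.get("pose_id", pd.Series(range(len(frame))))
    return TrainingSet(
        features=frame[columns].to_numpy(),
        labels=frame["label"].to_numpy(dtype=float),
        group_id=groups.to_numpy(),
        schema_id=schema_id(scheme),
    )


def filter_training_poses(training_set: TrainingSet, max_label: float = 10.0) -> TrainingSet:
    """Drop poses whose RMSD label exceeds ``max_label`` (strictly: 10.0 Å is kept).

    Raises :class:`TrainingError` if nothing survives.
    """
    keep = training_set.labels <= max_label
    n_removed = int((~keep).sum())
    if not keep.any():
        raise TrainingError(f"all {len(training_set)} poses exceed the {max_label} Å label cap")
    if n_removed:
        logger.info("label filter: removed %d of %d poses with RMSD > %.1f Å",
                    n_removed, len(training_set), max_label)
    return TrainingSet(
        features=training_set.features[keep],
        labels=training_set.labels[keep],
        group_id=training_set.group_id[keep],
        schema_id=training_set.schema_id,
    )


@dataclass
class SFCTModel:
    """A fitted correction-term regressor with its feature schema and provenance."""

    estimator: AdaBoostRegressor | None
    schema_id: str
    hyperparams: SFCTHyperparams
    training_summary: dict = field(default_factory=dict)

    @property
    def is_fitted(self) -> bool:
        return self.estimator is not None and hasattr(self.estimator, "estimators_")


def train_sfct(training_set: TrainingSet, hyperparams: SFCTHyperparams | None = None) -> SFCTModel:
    """Fit the AdaBoost.R2 ensemble of random forests on a filtered training set.

    Deterministic for a fixed ``hyperparams.seed``.  Requires at least two
    distinct label values and a feature length >= ``max_features``.
    """
    hp = hyperparams or SFCTHyperparams()
    n_poses, n_features = training_set.features.shape
    if n_features < hp.max_features:
        raise TrainingError(
            f"max_features={hp.max_features} exceeds feature length {n_features}"
        )
    if len(np.unique(training_set.labels)) < 2:
        raise TrainingError("degenerate training target: all labels are equal")

    base = RandomForestRegressor(
        n_estimators=hp.trees_per_forest,
        max_features=hp.max_features,
        max_depth=hp.max_depth,
        oob_score=hp.use_oob,
        bootstrap=True,
        n_jobs=1,
        random_state=hp.seed,
    )
    ensemble = AdaBoostRegressor(
        estimator=base,
        n_estimators=hp.n_boost_rounds,
        loss=hp.boosting_loss,
        random_state=hp.seed,
    )
    ensemble.fit(training_set.features, training_set.labels)
    summary = {
        "n_poses": int(n_poses),
        "n_features": int(n_features),
        "label_min": float(training_set.labels.min()),
        "label_max": float(training_set.labels.max()),
        "n_groups": int(len(np.unique(training_set.group_id))),
    }
    return SFCTModel(ensemble, training_set.schema_id, hp, summary)


def _as_feature_matrix(model: SFCTModel, features) -> np.ndarray:
    if isinstance(features, FeatureVector):
        features = [features]
    if isinstance(features, (list, tuple)) and all(isinstance(f, FeatureVector) for f in features):
        for f in features:
            if f.schema_id != model.schema_id:
                raise SchemaError(
                    f"feature schema {f.schema_id} does not match model schema {model.schema_id}"
                )
        if not features:
            return np.empty((0, model.training_summary.get("n_features", 0)))
        return np.vstack([f.counts for f in features])
    matrix = np.asarray(features, dtype=float)
    if matrix.ndim == 1:
        matrix = matrix[None, :]
    if matrix.size and matrix.shape[1] != model.training_summary.get("n_features", matrix.shape[1]):
        raise SchemaError(
            f"feature width {matrix.shape[1]} does not match model "
            f"({model.training_summary.get('n_features')})"
        )
    return matrix


def predict_sfct(model: SFCTModel, features) -> np.ndarray:
    """Predict pose RMSD (Å, clamped at 0) for a batch of feature vectors.

    Accepts FeatureVector(s) (schema-checked) or a raw (n, n_bins) array.
    An empty batch yields an empty array.
    """
    if not model.is_fitted:
        raise ModelStateError("model is not fitted")
    matrix = _as_feature_matrix(model, features)
    if matrix.shape[0] == 0:
        return np.empty(0)
    pred = model.estimator.predict(matrix)
    return np.clip(pred, 0.0, None)


def feature_importance(model: SFCTModel, scheme: ShellScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Per-bin ensemble importances as a (residue, element, shell, importance) table.

    Importances are the boosting-weight-averaged forest impurity
    importances; they are non-negative and sum to 1.  Pivot on
    (residue_class, element_class) vs shell for heatmaps of which
    contacts drive the RMSD prediction.
    """
    if not model.is_fitted:
        raise ModelStateError("model is not fitted")
    if schema_id(scheme) != model.schema_id:
        raise SchemaError("scheme does not match the model's feature schema")
    labels = feature_schema(scheme)
    importances = model.estimator.feature_importances_
    return pd.DataFrame(
        {
            "residue_class": [r for r, _, _ in labels],
            "element_class": [e for _, e, _ in labels],
            "shell": [s for _, _, s in labels],
            "importance": importances,
        }
    )


def save_model(model: SFCTModel, path: str | Path) -> None:
    """Persist a fitted model as a single versioned artifact."""
    if not model.is_fitted:
        raise ModelStateError("refusing to save an unfitted model")
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "schema_id": model.schema_id,
        "hyperparams": model.hyperparams,
        "training_summary": model.training_summary,
        "estimator": model.estimator,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path, expect_schema_id: str | None = None) -> SFCTModel:
    """Load a persisted model; errors on truncation, version or schema mismatch."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # noqa: BLE001 - any unpickling failure is a format error
        raise ModelFormatError(f"cannot read model artifact {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ModelFormatError(f"{path} is not a version-{_MODEL_FORMAT_VERSION} model artifact")
    if expect_schema_id is not None and payload["schema_id"] != expect_schema_id:
        raise ModelFormatError(
            f"model schema {payload['schema_id']} does not match expected {expect_schema_id}"
        )
    return SFCTModel(
        payload["estimator"], payload["schema_id"], payload["hyperparams"],
        payload.get("training_summary", {}),
    )


def group_train_test_split(
    training_set: TrainingSet, test_fraction: float = 0.2, seed: int = 0
) -> tuple[TrainingSet, TrainingSet]:
    """Split by native complex so no complex contributes poses to both sides."""
    groups = np.unique(training_set.group_id)
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(groups)
    n_test = max(1, int(round(test_fraction * len(groups))))
    test_groups = set(shuffled[:n_test].tolist())
    in_test = np.array([g in test_groups for g in training_set.group_id])
    if in_test.all() or not in_test.any():
        raise TrainingError("group split produced an empty side; need >= 2 groups")

    def subset(mask: np.ndarray) -> TrainingSet:
        return TrainingSet(
            features=training_set.features[mask],
            labels=training_set.labels[mask],
            group_id=training_set.group_id[mask],
            schema_id=training_set.schema_id,
        )

    return subset(~in_test), subset(in_test)
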