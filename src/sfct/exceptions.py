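"""Exception hierarchy for the sfct package."""


class SfctError(Exception):
    """Base class for all package errors."""


class StructureParseError(SfctError):
    """A structure file could not be parsed; the message names the offending line."""


class EmptyStructureError(SfctError):
    """A structure contained no usable heavy atoms after filtering."""


class TopologyError(SfctError):
    """Two poses (or a pose set) do not share one molecular topology."""


class SchemaError(SfctError):
    """A feature vector's schema does not match the model's schema."""


class TrainingError(SfctError):
    """The training set is empty, degenerate, or inconsistent with the hyperparameters."""


class ModelStateError(SfctError):
    """An operation requiring a fitted model was called on an unfitted one."""


class ModelFormatError(SfctError):
    """A persisted model artifact is truncated, unversioned, or schema-incompatible."""


class ScoringError(SfctError):
    """Missing or non-finite docking scores where scoring requires them."""


class MetricError(SfctError):
    """An evaluation metric is undefined on the given input (e.g. no actives)."""


class GenerationError(SfctError):
    """The synthetic generator failed to place a structure within its retry budget."""
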