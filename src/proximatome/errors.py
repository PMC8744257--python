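"""Exception hierarchy shared across the pipeline.

Every error raised on invalid user input derives from :class:`ProximatomeError`
so callers (and the CLI) can distinguish validation failures from bugs.
"""


class ProximatomeError(Exception):
    """Base class for all package-level errors."""


class ValidationError(ProximatomeError):
    """Input violates a documented invariant or precondition."""


class DesignMismatchError(ValidationError):
    """Count matrix columns do not match the sample design."""


class DuplicateKeyError(ValidationError):
    """Duplicate identifier where uniqueness is required."""


class EmptyInputError(ValidationError):
    """An input table or record list is empty where content is required."""


class SchemaError(ValidationError):
    """Required columns are missing from a table."""


class InvariantError(ValidationError):
    """A domain-type invariant is violated (e.g. MTS outside the protein)."""


class UndefinedRatioError(ValidationError):
    """Fold change undefined: zero control mean with zero pseudocount."""


class InsufficientPermutationsError(ValidationError):
    """Too few samples for a permutation test."""


class AnnotationGapError(ValidationError):
    """Proteins lack a required annotation (e.g. length)."""

    def __init__(self, message, missing_ids=()):
        super().__init__(message)
        self.missing_ids = list(missing_ids)


class DegenerateDistributionError(ValidationError):
    """Zero variance where a spread is required (z-scoring)."""


class InsufficientOverlapError(ValidationError):
    """Too few shared proteins for a paired comparison."""


class MissingNormalizerError(ValidationError):
    """Reference target absent from a qPCR computation."""


class AnchorError(ValidationError):
    """t = 0 anchor missing from a decay time course."""


class ConfigError(ValidationError):
    """Invalid simulation or pipeline configuration."""


class StageFailureError(ProximatomeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
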