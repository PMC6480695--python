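"""Exception hierarchy shared across the pipeline stages."""


class IcbBenchError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IcbBenchError):
    """Simulation or run configuration is internally inconsistent."""


class SchemaError(IcbBenchError):
    """A table does not match the expected column/row layout."""


class ParseError(SchemaError):
    """A cell could not be parsed; the message carries row/column coordinates."""


class MissingGeneError(IcbBenchError):
    """A required gene symbol is absent from the expression matrix."""


class MissingSignatureError(IcbBenchError):
    """None of a gene set's members are present in the expression matrix."""


class IdentifierMismatchError(IcbBenchError):
    """Patient identifiers in one table do not match the cohort's."""


class IdentifierCollisionError(IcbBenchError):
    """The same patient identifier appears in more than one cohort."""


class VocabularyError(IcbBenchError):
    """A clinical response category is outside the canonical vocabulary."""


class EmptyInputError(IcbBenchError):
    """An operation that requires at least one record received none."""


class DegenerateLabelsError(IcbBenchError):
    """Both outcome classes are required but only one is present."""


class UndefinedCorrelationError(IcbBenchError):
    """Pearson correlation is undefined (constant marker column)."""


class MissingVoteError(IcbBenchError):
    """A marker call required for majority voting is missing."""


class ReliabilityError(IcbBenchError):
    """Too many cross-validation iterations were degenerate to trust the means."""


class PipelineError(IcbBenchError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
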