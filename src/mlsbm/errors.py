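"""Exception hierarchy shared across the package."""


class MlsbmError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(MlsbmError):
    """Mismatched vertex counts or array shapes."""


class LabelError(MlsbmError):
    """Cluster label outside the valid range [0, K)."""


class ParameterError(MlsbmError):
    """Invalid model or run parameter (non-positive hyperparameter, bad K, ...)."""


class DegenerateNetworkError(MlsbmError):
    """A network unusable for the requested evaluation (e.g. no links for AUC)."""


class ConsistencyError(MlsbmError):
    """Internal sufficient statistics no longer match the partition."""


class MetadataError(MlsbmError):
    """Missing or malformed per-vertex metadata."""


class ParseError(MlsbmError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
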