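"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`MrfPrioError`, so callers (and the CLI) can distinguish domain
errors from programming errors.
"""


class MrfPrioError(Exception):
    """Base class for all package errors."""


class ParseError(MrfPrioError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ResolutionError(MrfPrioError):
    """A gene symbol could not be resolved against the universe."""


class DimensionError(MrfPrioError):
    """Inconsistent array / universe dimensions."""


class ConfigurationError(MrfPrioError):
    """Invalid sampler or pipeline configuration."""


class ConsistencyError(MrfPrioError):
    """Inputs violate a cross-object invariant (e.g. gene-set containment)."""


class EstimationError(MrfPrioError):
    """Pseudo-likelihood parameter estimation failed or is degenerate."""


class EvaluationError(MrfPrioError):
    """Evaluation cannot proceed (e.g. only one label class present)."""


class CapabilityError(MrfPrioError):
    """Requested exact computation exceeds what enumeration can handle."""
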