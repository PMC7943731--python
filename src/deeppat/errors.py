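"""Exception hierarchy for deeppat.

Exit-code mapping used by the CLI lives in :mod:`deeppat.cli`; library code
raises these types and never calls ``sys.exit``.
"""


class DeepPATError(Exception):
    """Base class for all deeppat errors."""


class InvalidArgumentError(DeepPATError, ValueError):
    """A parameter value violates a documented precondition."""


class InvalidGeometryError(DeepPATError, ValueError):
    """An acquisition geometry is unphysical (pixels outside the ring, ...)."""


class DimensionMismatchError(DeepPATError, ValueError):
    """Operands have incompatible shapes."""


class DegenerateRangeError(DeepPATError, ValueError):
    """An image with no intensity range was given where range is required."""


class ArchitectureError(DeepPATError, ValueError):
    """A network specification is inconsistent with the input size."""


class SolverFailureError(DeepPATError, RuntimeError):
    """An iterative solver diverged; the objective trace is attached."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class TrainingDivergedError(DeepPATError, RuntimeError):
    """Training produced a non-finite loss; the history is attached."""

    def __init__(self, message: str, history=None):
        super().__init__(message)
        self.history = history


class ConfigError(DeepPATError, ValueError):
    """A benchmark configuration file is malformed."""
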