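"""Exception hierarchy for gadoflux.

Exit-code mapping used by the CLI: validation errors -> 2,
convergence/simulation failures -> 3.
"""


class GadofluxError(Exception):
    """Base class for all package errors."""


class ValidationError(GadofluxError):
    """Invalid input data or configuration (CLI exit code 2)."""


class FormatError(ValidationError):
    """A file could not be parsed into the expected layout."""


class InsufficientDataError(ValidationError):
    """A patient record lacks the observations an analysis requires."""


class SimulationError(GadofluxError):
    """The forward model could not be evaluated (CLI exit code 3)."""


class ConvergenceError(GadofluxError):
    """An optimizer failed to converge (CLI exit code 3)."""
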