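"""Exception hierarchy for the timMRD pipeline.

Validation errors indicate malformed or inconsistent user input; runtime
errors indicate a computation that could not be completed (optimizer
failure, undefined summary). The CLI maps these onto exit codes.
"""


class TimmrdError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(TimmrdError):
    """Input violates a documented contract (bad counts, bad coordinates...)."""


class ParseError(ValidationError):
    """A text input file could not be parsed; message names the line."""


class InsufficientDataError(ValidationError):
    """Too few samples / observations for the requested estimate."""


class UndefinedResultError(TimmrdError):
    """The requested summary is undefined on this input (e.g. no covered block)."""


class ConstraintError(ValidationError):
    """Mixture parameters outside the feasible simplex."""


class UnscoreablePatientError(TimmrdError):
    """No block survives patient-specific marker selection."""


class FitError(TimmrdError):
    """Likelihood maximization or score computation failed."""
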