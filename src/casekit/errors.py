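"""Exception hierarchy for casekit.

Every error raised on purpose derives from :class:`CasekitError` so callers can
catch the package's failures without catching programming bugs.
"""


class CasekitError(Exception):
    """Base class for all casekit errors."""


class ParameterError(CasekitError, ValueError):
    """A numeric parameter is outside its valid domain (e.g. rho >= 1)."""


class ConfigError(CasekitError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class EstimationError(CasekitError):
    """Too little data to estimate a model parameter reliably."""


class PairingError(CasekitError):
    """Treatment/control inputs do not refer to the same SNP and individual."""


class CalibrationError(CasekitError):
    """The control-versus-control null set is missing, too small, or degenerate."""


class InsufficientDataError(CasekitError):
    """Fewer observations than the minimum a statistic requires."""


class ValidationError(CasekitError):
    """A samples manifest or input table fails structural validation."""


class ParseError(CasekitError):
    """A malformed input file; carries the offending 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
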