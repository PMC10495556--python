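"""Exception hierarchy for rpmplan."""


class RpmPlanError(Exception):
    """Base class for all rpmplan errors."""


class InvalidParameterError(RpmPlanError, ValueError):
    """A model parameter violates its invariant (e.g. negative count)."""


class InvalidAxisError(RpmPlanError, ValueError):
    """A scenario modification names an unknown or inapplicable axis."""


class LogValidationError(RpmPlanError, ValueError):
    """A historical-log CSV failed validation.

    ``line`` is the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class NoValidPeriodsError(RpmPlanError, ValueError):
    """No period in the log has flagged > 0, so the ratio is undefined."""


class UnknownPresetError(RpmPlanError, KeyError):
    """An unknown scenario preset name was requested."""
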