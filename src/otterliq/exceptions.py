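"""Exception hierarchy for the toolkit.

All toolkit errors derive from :class:`OtterError` so callers (and the CLI)
can distinguish data problems from programming faults.
"""


class OtterError(Exception):
    """Base class for all toolkit errors."""


class FormatError(OtterError):
    """A table or file does not conform to its declared dialect."""


class ParseError(FormatError):
    """A specific row or field failed to parse; carries location context."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(OtterError):
    """A domain object violates one of its invariants."""


class InfeasibleModelError(OtterError):
    """Filter-model parameters imply a specificity outside (0, 1)."""


class ConfigurationError(OtterError):
    """Missing or inconsistent run configuration (e.g. no pre-test odds for a gene)."""
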