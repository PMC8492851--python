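"""Exception hierarchy shared across the pipeline."""


class OrgstateError(Exception):
    """Base class for all orgstate errors."""


class ConfigurationError(OrgstateError, ValueError):
    """Invalid parameter values or inconsistent configuration."""


class FormatError(OrgstateError, ValueError):
    """Malformed input files or tables (dimension mismatches, schema violations)."""


class EmptyResultError(OrgstateError, RuntimeError):
    """An operation removed or excluded everything.

    Carries an optional ``report`` attribute describing what was removed.
    """

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class NormalizationError(OrgstateError, ValueError):
    """Normalization preconditions violated (e.g. a zero-total cell)."""
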