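"""Exception hierarchy shared across the package."""


class OxibenchError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OxibenchError, ValueError):
    """A domain object or configuration failed validation.

    The message always names the offending field.
    """


class NoCardiacSignalError(OxibenchError, RuntimeError):
    """No cardiac component could be detected in a signal window."""


class UndefinedResultError(OxibenchError, RuntimeError):
    """A metric is undefined for the given inputs (e.g. no valid readings)."""
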