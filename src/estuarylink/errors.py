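"""Exception types shared across the package."""


class EstuaryLinkError(Exception):
    """Base class for all package errors."""


class ValidationError(EstuaryLinkError, ValueError):
    """An input object or configuration field violates its contract."""


class RangeError(EstuaryLinkError, ValueError):
    """A requested date or window falls outside the available record."""


class FitError(EstuaryLinkError, RuntimeError):
    """Model fitting refused or failed to converge."""


class UndefinedMetricError(EstuaryLinkError, ValueError):
    """A goodness-of-fit metric is undefined for the given inputs."""
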