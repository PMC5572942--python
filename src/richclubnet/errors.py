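"""Exception types raised across the package."""


class RichClubNetError(Exception):
    """Base class for package errors."""


class FormatError(RichClubNetError):
    """A file does not have the expected shape or layout."""


class ValidationError(RichClubNetError):
    """An input violates a documented invariant (negative weight, asymmetry, ...)."""


class DisconnectedNetworkError(RichClubNetError):
    """A computation requiring a connected network received a disconnected one.

    Carries the component labels so callers can identify the offending parts.
    """

    def __init__(self, message, component_labels=None):
        super().__init__(message)
        self.component_labels = component_labels


class DegenerateMetricError(RichClubNetError):
    """A metric is undefined on this input (e.g. zero variance of endpoint strengths)."""
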