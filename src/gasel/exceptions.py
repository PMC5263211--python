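"""Exception hierarchy shared across the package."""


class GaselError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GaselError, ValueError):
    """Invalid simulation or run configuration."""


class DomainError(GaselError, ValueError):
    """Argument outside the mathematical domain of a closed-form expression."""


class AlignmentError(GaselError, ValueError):
    """Line or marker identifiers of two inputs do not match."""


class EmptyPanelError(GaselError, ValueError):
    """An operation removed every marker (or was handed an empty panel)."""


class ConvergenceWarning(UserWarning):
    """An iterative routine stopped before reaching its tolerance."""
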