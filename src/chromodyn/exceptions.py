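"""Exception hierarchy shared across the toolkit."""


class ChromodynError(Exception):
    """Base class for all package errors."""


class FormatError(ChromodynError):
    """A delimited-text input violates the expected layout."""


class WindowError(ChromodynError):
    """A trajectory window is too short for the requested computation."""


class InsufficientDataError(ChromodynError):
    """Not enough observations to fit the requested model."""


class ScenarioError(ChromodynError):
    """Unknown benchmark scenario name."""


class SpecError(ChromodynError):
    """Inconsistent simulation specification."""
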