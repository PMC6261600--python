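"""Exception hierarchy.

Everything user-facing derives from :class:`ValidationError` so the CLI can
map bad inputs to a single exit code.
"""


class ValidationError(ValueError):
    """Invalid input to an operation (bad shapes, values, configuration)."""


class StabilityError(ValidationError):
    """Lag matrix has a root on or outside the unit circle."""


class FormatError(ValidationError):
    """Malformed search-interest CSV (gapped months, bad cells, ...)."""


class ConfigError(ValidationError):
    """Malformed run configuration; carries the offending field name."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field '{field}': {message}")
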