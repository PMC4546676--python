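"""Exception types shared across the package."""


class TroutsimError(Exception):
    """Base class for package errors."""


class RegimeFormatError(TroutsimError, ValueError):
    """A regime or reach file violates the expected format.

    Carries the offending row number (0-based data row) when known.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class ConfigError(TroutsimError, ValueError):
    """A run configuration failed validation; message includes field paths."""


class InsufficientDataError(TroutsimError, ValueError):
    """A statistical routine received too few observations."""
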