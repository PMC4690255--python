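"""Exception hierarchy with CLI exit codes.

Exit-code convention: 0 success, 2 input error, 3 configuration error,
4 internal error.
"""


class ScreenError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 4


class InputError(ScreenError):
    """Bad input data: missing files, malformed records, unknown keys."""

    exit_code = 2


class FormatError(InputError):
    """A stream or file does not conform to its documented layout."""


class PlantingError(InputError):
    """A targeting signal cannot be planted into the given sequence."""


class ConfigError(ScreenError):
    """Invalid configuration or parameter values."""

    exit_code = 3


class CalibrationError(ScreenError):
    """Null-score calibration failed (e.g. degenerate score variance)."""
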