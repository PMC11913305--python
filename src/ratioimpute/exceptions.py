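"""Exception hierarchy.

Every error raised by this package derives from :class:`RatioImputeError`,
so callers (and the CLI exit-code mapping) can distinguish configuration
problems, numeric-domain failures and degenerate data from plain bugs.
"""


class RatioImputeError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(RatioImputeError, ValueError):
    """A distribution / regression / sampling spec violates its invariants."""


class ConfigError(RatioImputeError, ValueError):
    """A run configuration is malformed (unknown keys, bad ranges)."""


class SamplingError(RatioImputeError, ValueError):
    """A sample cannot be drawn as requested (e.g. n > N)."""


class ScreeningError(SamplingError):
    """The multicollinearity screen exhausted its retry budget."""

    def __init__(self, message: str, last_r: float, tries: int):
        super().__init__(message)
        self.last_r = last_r
        self.tries = tries


class DegenerateDataError(RatioImputeError, ValueError):
    """Too few usable rows for the requested operation."""


class NumericDomainError(RatioImputeError, ArithmeticError):
    """A formula was evaluated outside its numeric domain
    (non-positive denominator, zero response in MAPE, singular fit)."""
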