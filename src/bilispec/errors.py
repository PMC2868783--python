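"""Exception hierarchy shared across the package.

``ValidationError`` maps to CLI exit code 2, ``NumericalError`` to 3.
"""


class BilispecError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BilispecError, ValueError):
    """Invalid user input: out-of-domain values, malformed tables, bad grids."""


class NumericalError(BilispecError, ArithmeticError):
    """A numerical procedure failed (no bracket, rank deficiency, ...)."""
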