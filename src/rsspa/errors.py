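"""Exception hierarchy shared across the package.

``ValidationError`` covers bad user input (unknown pollutant codes, malformed
CSV, out-of-range parameters); ``DegenerateWindowError`` covers numerical
degeneracy (a constant window makes the rescaled range undefined). The CLI
maps these to exit codes 2 and 3 respectively.
"""


class RsspaError(Exception):
    """Base class for all package errors."""


class ValidationError(RsspaError, ValueError):
    """Invalid input: domain violation, lookup failure, or malformed data."""


class DegenerateWindowError(RsspaError, ArithmeticError):
    """A window has zero standard deviation, so R/S is undefined there."""

    def __init__(self, start: int, length: int):
        self.start = start
        self.length = length
        super().__init__(
            f"constant window of length {length} starting at index {start}: "
            "standard deviation is zero, R/S undefined"
        )
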