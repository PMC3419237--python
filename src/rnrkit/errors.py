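"""Exception hierarchy shared across the toolkit.

The CLI maps these onto exit codes: usage errors are handled by click
(exit 2), :class:`DataFormatError` exits 3 and :class:`NumericalError`
exits 4.
"""


class RnrkitError(Exception):
    """Base class for all rnrkit errors."""


class DomainError(RnrkitError, ValueError):
    """An argument violates a documented precondition."""


class DataFormatError(RnrkitError, ValueError):
    """An input file or table does not match the expected dialect."""


class NumericalError(RnrkitError, ArithmeticError):
    """A numerical procedure failed (non-convergence, degenerate input)."""


class FeatureDetectionError(RnrkitError, ValueError):
    """Spectral feature extraction found fewer features than required.

    Carries the partial result so callers can inspect what was found.
    """

    def __init__(self, message: str, found: dict | None = None):
        super().__init__(message)
        self.found = found or {}
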