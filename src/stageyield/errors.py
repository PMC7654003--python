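"""Exception hierarchy for the stageyield package."""


class StageYieldError(Exception):
    """Base class for all package-specific errors."""


class SpectrumParseError(StageYieldError):
    """A spectrum file contained a non-numeric payload row."""


class CoverageError(StageYieldError):
    """A spectrum does not cover the wavelength range needed for band extraction."""


class UndefinedIndexError(StageYieldError):
    """A vegetation-index formula hit a zero denominator."""


class FitConvergenceError(StageYieldError):
    """Iterative curve fitting failed to converge.

    Carries the last parameter iterate (if any) in ``last_params``.
    """

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class ValidationError(StageYieldError):
    """An input table, matrix or config violated its invariants."""
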