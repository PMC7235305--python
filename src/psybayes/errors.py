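"""Exception types shared across the package."""


class PsybayesError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PsybayesError, ValueError):
    """Input data or settings violate a model's preconditions."""


class DegenerateChainError(PsybayesError, ValueError):
    """Diagnostics requested on chains with zero within-chain variance."""


class UnknownParameterError(PsybayesError, KeyError):
    """A parameter name was not found; carries the valid names."""

    def __init__(self, name: str, available: list[str]):
        self.name = name
        self.available = list(available)
        super().__init__(
            f"unknown parameter {name!r}; available parameters: {', '.join(available)}"
        )


class UnsupportedOperationError(PsybayesError, TypeError):
    """Operation not defined for this fit type (e.g. subject draws of a flat model)."""


class AlignmentError(PsybayesError, ValueError):
    """Draw vectors of unequal length cannot be compared index-wise.

    Re-run the fits with identical chains/iter settings so draws align.
    """


class UndefinedMeanError(PsybayesError, ValueError):
    """Circular mean undefined: resultant vector length is (numerically) zero."""


class CompatibilityError(PsybayesError, TypeError):
    """Fits of different model families cannot be compared distribution-wise."""


class InitializationError(PsybayesError, RuntimeError):
    """Sampler failed to find a finite starting point."""
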