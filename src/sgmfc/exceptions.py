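"""Exception hierarchy shared across the package."""


class SGMError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(SGMError, ValueError):
    """Input carries no usable signal (all-zero weights, isolated regions, ...)."""


class ConfigurationError(SGMError, ValueError):
    """Inconsistent or incomplete configuration (e.g. homolog floor without pairs)."""


class DomainError(SGMError, ValueError):
    """Argument outside its physical domain (negative speed, band above Nyquist, ...)."""


class NumericalDegeneracyError(SGMError, ArithmeticError):
    """Eigendecomposition or another numerical step failed beyond tolerance."""


class NearResonanceError(SGMError, ArithmeticError):
    """A harmonic's frequency-response denominator vanished; identifies the mode."""

    def __init__(self, mode_index: int, magnitude: float):
        self.mode_index = mode_index
        self.magnitude = magnitude
        super().__init__(
            f"near-resonant harmonic k={mode_index}: |j*omega + tau_g^-1 lambda_k Fg| "
            f"= {magnitude:.3e} below tolerance"
        )


class NormalizationError(SGMError, ArithmeticError):
    """Diagonal of the band CSD sum is not strictly positive."""


class SegmentationError(SGMError, ValueError):
    """Recording too short for the requested epoching."""


class DegenerateScaleError(SGMError, ValueError):
    """Constant input where a non-degenerate value range is required (minmax)."""


class UndefinedMetricError(SGMError, ArithmeticError):
    """Metric denominator (variance / null spread) is zero."""


class InstabilityError(SGMError, RuntimeError):
    """Neural-mass integration blew up; carries the offending parameters."""

    def __init__(self, message: str, params=None):
        self.params = params
        super().__init__(message)
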