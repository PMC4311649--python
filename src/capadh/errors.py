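"""Exception and warning hierarchy for the CAT analysis toolkit.

Exit-code mapping used by the command line front end:
config errors -> 2, data/extraction errors -> 3, numerical errors -> 4.
"""


class CapadhError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(CapadhError):
    """Invalid or incomplete analysis/scenario configuration."""


class DataError(CapadhError):
    """Problems with the measured data (images, point sets, sequences)."""


class DomainError(DataError):
    """Input outside the mathematical domain of an operation."""


class FitDegeneracyError(DataError):
    """Point set cannot constrain the meniscus profile (collinear, one flank
    without an axis estimate, too few points)."""


class FitConvergenceError(CapadhError):
    """Profile fit failed to converge; carries the best iterate."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class InsufficientDataError(DataError):
    """Too few analyzable frames for the requested estimator."""


class ThresholdingError(DataError):
    """Automatic threshold selection failed (non-bimodal histogram)."""


class BaselineDetectionError(DataError):
    """No flat far-field liquid surface found in the silhouette."""


class TrackingLostError(DataError):
    """Cross-correlation peak below the confidence floor."""


class AngleMeasurementError(DataError):
    """Fiber centerline fit degenerate; bending angle unresolvable."""


class GenerationError(CapadhError):
    """Synthetic family is unphysical (e.g. decreasing surface energy)."""


class RenderError(CapadhError):
    """Synthetic scene does not fit the camera field of view."""


class NumericalError(CapadhError):
    """Quadrature / ODE solver failed to converge; carries diagnostics."""


class NonMonotoneEnergyWarning(UserWarning):
    """Meniscus energy is not monotone in tip height beyond noise level."""


class SmallDeflectionWarning(UserWarning):
    """Bending angle beyond the small-deflection validity bound."""
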