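"""Exception types shared across the package."""


class CarelocError(Exception):
    """Base class for package-specific errors."""


class ValidationError(CarelocError, ValueError):
    """Invalid input data or configuration."""


class RealGeoUnavailableError(CarelocError, RuntimeError):
    """Raised when real-geo mode is requested but the geospatial backend
    (hexagonal indexing + equal-area projection) is not installed.
    Synthetic (planar) mode never raises this."""


class InfeasibleError(CarelocError, RuntimeError):
    """Raised when an optimization model has no feasible solution and the
    caller asked for a solution object rather than a status."""
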