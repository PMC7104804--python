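"""Exception types shared across the package."""


class BraincamError(Exception):
    """Base class for package-specific errors."""


class ValidationError(BraincamError, ValueError):
    """Invalid data: bad cohort rows, mismatched spaces, broken invariants."""


class DomainError(BraincamError, ValueError):
    """Argument outside its mathematical domain (non-positive factor, bad fractions...)."""


class ShapeError(BraincamError, ValueError):
    """Array shapes incompatible with the requested operation."""


class DimensionalityError(BraincamError, ValueError):
    """Image is not a 3D volume (e.g. a 4D time series)."""


class ConfigurationError(BraincamError, ValueError):
    """Inconsistent network or run configuration."""


class StateError(BraincamError, RuntimeError):
    """Operation applied to an object in the wrong processing stage."""


class DegenerateMapError(BraincamError, ValueError):
    """A localization map with zero variance cannot be standardized."""
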