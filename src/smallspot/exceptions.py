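"""Exception hierarchy shared across the package."""


class SmallspotError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SmallspotError, ValueError):
    """A numeric argument violates its documented domain."""


class InvalidInputError(SmallspotError, ValueError):
    """A data structure (trial table, measurement list, ...) is unusable."""


class GeometryError(SmallspotError):
    """Mosaic/stimulus geometry cannot support the requested computation."""


class MissingClassError(SmallspotError):
    """A cone class required by the computation is absent from the mosaic."""


class ResolutionError(SmallspotError):
    """A numerical grid is too small or too coarse for the requested optics."""


class NonIdentifiableError(SmallspotError):
    """A model fit has no interior maximum (e.g. all-seen staircase data)."""


class SeparationError(SmallspotError):
    """Complete separation in a logistic fit; names the offending predictor."""


class ConfigError(SmallspotError, ValueError):
    """A run configuration failed validation."""
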