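"""Exception hierarchy for tfusim."""


class TfusimError(Exception):
    """Base class for all tfusim errors."""


class InvalidConfigError(TfusimError):
    """A scene or grid configuration violates a validity constraint."""


class ConfigSchemaError(InvalidConfigError):
    """A configuration file is missing keys or has malformed values."""


class GeometryError(TfusimError):
    """Transducer or plate geometry cannot be realized on the grid."""


class DivergenceError(TfusimError):
    """The explicit time stepping produced non-finite or blown-up pressures."""


class FlatFieldError(TfusimError):
    """An amplitude field has no unique focal maximum."""


class OpenRegionError(TfusimError):
    """The half-amplitude focal region reaches the domain boundary."""


class DegenerateDataError(TfusimError):
    """Fit input data are degenerate (e.g. constant abscissa)."""


class FitConvergenceError(TfusimError):
    """Nonlinear least squares failed to converge."""


class UndefinedCorrelationError(TfusimError):
    """Correlation between fitted curves is undefined (constant curve)."""


class UnknownFixtureError(TfusimError):
    """Requested test fixture name is not in the documented set."""
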