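"""Exception hierarchy shared across the pipeline stages."""


class PwpeError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(PwpeError):
    """A user-supplied specification or config value is invalid."""


class NumericalDomainError(PwpeError):
    """A computation left its numerical domain (overflow, non-finite state)."""


class InadmissibleParameterError(NumericalDomainError):
    """An HGF parameter set produced a non-positive posterior precision."""


class AlignmentError(PwpeError):
    """Trial-wise inputs that must share a length do not."""


class DesignError(PwpeError):
    """A regression design matrix is degenerate (zero variance, collinear)."""


class ProjectionError(PwpeError):
    """Channel montage cannot be projected onto the 2D scalp grid."""
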