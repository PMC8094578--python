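"""Exception hierarchy shared by all gammafs modules."""


class GammaFSError(Exception):
    """Base class for all gammafs errors."""


class ValidationError(GammaFSError, ValueError):
    """Malformed or out-of-contract input (non-finite values, bad shapes,
    unknown feature names, unparseable files, ...)."""


class DegenerateClassError(GammaFSError, ValueError):
    """A class has too few observations to estimate its covariance ellipsoid."""


class DegenerateGeometryError(GammaFSError, ValueError):
    """Both class ellipsoids are point masses: the separability normalization
    factor is zero and the metric is undefined."""


class ParseError(ValidationError):
    """A data file could not be parsed; the message names the offending line."""
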