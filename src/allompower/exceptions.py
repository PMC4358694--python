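"""Exception hierarchy shared across the package."""


class AllompowerError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AllompowerError, ValueError):
    """A delimited input file contains a malformed cell."""


class ValidationError(AllompowerError, ValueError):
    """Input data violate a structural invariant (positivity, vocabulary, ...)."""


class ConfigurationError(AllompowerError, ValueError):
    """A parameter is outside its legal domain (log base, R^2 range, ...)."""


class DegenerateDataError(AllompowerError, ValueError):
    """A regression input has zero variance or zero correlation."""


class SampleSizeError(AllompowerError, ValueError):
    """Too few observations for the requested operation."""


class InfeasibleSubsampleError(AllompowerError, RuntimeError):
    """A binned or size-class subsample cannot be drawn at the requested n."""


class FitError(AllompowerError, RuntimeError):
    """Nonlinear model fitting failed or has too few usable points."""
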