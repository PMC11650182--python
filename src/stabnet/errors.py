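"""Exception hierarchy.

Every error raised by the package derives from :class:`StabnetError`, so
callers (notably the bootstrap loop, which must count per-replicate
failures without dying) can catch one type.
"""


class StabnetError(Exception):
    """Base class for all stabnet errors."""


class SchemaError(StabnetError):
    """Table/roster structure mismatch (missing, extra or unknown columns)."""


class ParseError(StabnetError):
    """A cell could not be parsed as a number; carries row/column coordinates."""


class ValidationError(StabnetError):
    """A value violates a roster constraint (bounds, enumerations, shapes)."""


class ConfigError(StabnetError):
    """Invalid pipeline configuration."""


class UnimputableError(StabnetError):
    """A column has no observed values and therefore cannot be imputed."""


class FitError(StabnetError):
    """A model fit failed or did not converge."""


class IdentifiabilityError(FitError):
    """Too few indicators for the requested factor model."""


class CollinearityError(StabnetError):
    """Rank-deficient covariate design; names the dependent columns."""


class NumericalError(StabnetError):
    """Singular or otherwise numerically degenerate input."""


class InsufficientSampleError(StabnetError):
    """Sample too small for the requested conditioning-set size."""


class PipelineError(StabnetError):
    """Too many bootstrap replicates failed; the run was aborted."""
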