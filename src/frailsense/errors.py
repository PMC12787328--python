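"""Exception hierarchy shared across the package."""


class FrailsenseError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(FrailsenseError):
    """A simulation or run configuration violates its invariants."""


class InsufficientDataError(FrailsenseError):
    """Too few samples/values for the requested computation."""


class InvalidFitError(FrailsenseError):
    """A distance-time regression is unusable (non-positive slope,
    degenerate time span, or a non-positive implied walk time)."""


class DegenerateTableError(FrailsenseError):
    """An agreement statistic is undefined for this contingency table
    (e.g. expected agreement equals 1, or a zero margin for phi)."""


class SchemaError(FrailsenseError):
    """A CSV/zone-map input does not match the documented schema."""
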