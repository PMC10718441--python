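"""Exception hierarchy.

All package-specific failures derive from :class:`ScaleStatsError` so callers
can catch one base class.  Schema/record errors are raised by corpus I/O,
domain errors by numerical routines, config errors by generators and the
pipeline.
"""


class ScaleStatsError(Exception):
    """Base class for all scalestats errors."""


class SchemaError(ScaleStatsError):
    """A corpus file does not match the expected CSV schema."""


class RecordError(ScaleStatsError):
    """A single scale record violates an invariant (e.g. non-monotone notes)."""


class DomainError(ScaleStatsError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ConfigError(ScaleStatsError):
    """A configuration object is inconsistent or infeasible."""
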