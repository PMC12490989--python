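"""Exception hierarchy.

Every error raised by the package derives from :class:`MetabonetError` so
callers (and the CLI exit-code mapping) can distinguish validation,
estimation and configuration failures.
"""


class MetabonetError(Exception):
    """Base class for all package errors."""


class SchemaError(MetabonetError):
    """A table does not conform to the 13-node cohort schema."""


class CohortValidationError(MetabonetError):
    """Subject-level data violates a hard cohort constraint (e.g. missing
    values in a node column)."""


class UnitsError(MetabonetError):
    """Unknown or inconsistent measurement units."""


class SampleSizeError(MetabonetError):
    """Too few subjects for the requested estimation."""


class DegenerateVariableError(MetabonetError):
    """A node column is constant (zero variance) and cannot enter a
    correlation matrix."""


class EstimationError(MetabonetError):
    """Numerical failure during network estimation (e.g. singular
    correlation matrix)."""


class UndefinedMetricError(MetabonetError):
    """A graph statistic is undefined for the given graph (e.g. diameter of
    an edgeless graph)."""


class GenerationError(MetabonetError):
    """The synthetic-cohort generator received infeasible parameters."""


class ConfigurationError(MetabonetError):
    """Invalid run configuration or unknown option value."""
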