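"""Exception hierarchy.

Every error raised by abarec derives from :class:`AbarecError`, so callers can
catch one type at a pipeline boundary. Subclasses also derive from the closest
builtin (KeyError, ValueError, ...) for idiomatic handling.
"""


class AbarecError(Exception):
    """Base class for all abarec errors."""


class NoSuchFixtureError(AbarecError, KeyError):
    """Requested fixture table id is not packaged."""


class CohortParseError(AbarecError, ValueError):
    """A cohort file could not be parsed; message carries file/field context."""


class MissingFeatureError(AbarecError, KeyError):
    """A feature required for the similarity vector is absent; names the field."""


class UndefinedSimilarityError(AbarecError, ValueError):
    """Cosine similarity undefined (zero-norm vector)."""


class DimensionMismatchError(AbarecError, ValueError):
    """Vectors or matrices have incompatible shapes."""


class InsufficientCohortError(AbarecError, ValueError):
    """Too few participants for the requested neighbourhood size."""


class MissingPlanError(AbarecError, KeyError):
    """A retrieved neighbour has no treatment plan at the requested level."""


class EmptyInteractionError(AbarecError, ValueError):
    """No patient-item interactions could be built from the cohort."""


class ConfigError(AbarecError, ValueError):
    """Invalid configuration value (spec, params, rating map, mask fraction...)."""


class UndefinedMetricError(AbarecError, ValueError):
    """A metric's denominator is zero or its preconditions fail."""


class DegenerateStructureError(AbarecError, ValueError):
    """A validation statistic is undefined on degenerate input."""


class NumericError(AbarecError, ArithmeticError):
    """Non-finite values or a singular solve during model fitting."""
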