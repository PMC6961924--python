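"""Exception hierarchy for the size-estimation pipeline.

Every stage raises from this tree so callers (and the CLI) can fail fast with
a single except clause while tests can pin down the precise failure mode.
"""


class KPSizeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(KPSizeError):
    """Invalid simulation or run configuration (bad probability, missing path)."""


class SchemaError(KPSizeError):
    """An input table violates its declared schema (missing column, bad value).

    Carries row-level context in the message where available.
    """


class EstimationError(KPSizeError):
    """A computation cannot produce a defined estimate (e.g. division by a
    zero proportion, fewer units than strata)."""


class UndefinedEstimateError(EstimationError):
    """Multiplier estimate is undefined: the survey proportion (or its lower
    confidence bound) is zero, so N = n/p blows up."""
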