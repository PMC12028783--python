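"""Exception hierarchy shared across the pipeline stages.

Every stage raises a subclass of :class:`AlleloscreenError` so callers (and
the CLI) can map failure modes to distinct exit codes.
"""


class AlleloscreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AlleloscreenError, ValueError):
    """Invalid design/run configuration (bad probabilities, unknown labels...)."""


class SchemaError(AlleloscreenError, ValueError):
    """An input table does not match the documented CSV schema."""


class DataValidationError(AlleloscreenError, ValueError):
    """Input values violate a stage precondition (negative counts, n3 > n7...)."""


class DegenerateDataError(AlleloscreenError, ValueError):
    """The computation is undefined on this input (zero variance, T = C = 0...)."""


class DegenerateWeightsError(DegenerateDataError):
    """All criteria carry zero information divergence; entropy weights undefined.

    Callers may pass ``on_degenerate="uniform"`` to fall back to equal weights.
    """
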