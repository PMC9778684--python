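"""Exception hierarchy.

Every error raised by the library derives from :class:`SoilPtfError` so
callers (and the CLI) can distinguish usage/input problems from numerical
failures.
"""


class SoilPtfError(Exception):
    """Base class for all library errors."""


class InputError(SoilPtfError, ValueError):
    """Invalid argument values, malformed records, missing predictors."""


class DomainError(InputError):
    """A physical quantity outside its admissible domain (pH, concentration...)."""


class UnknownCompoundError(InputError, KeyError):
    """Compound code not in the registry."""


class UnknownModelError(InputError, KeyError):
    """Coefficient-set provenance or lookup failure."""


class ConfigError(InputError):
    """Inconsistent generator/split configuration."""


class NumericalError(SoilPtfError, ArithmeticError):
    """Solver non-convergence or other numerical failure; never silent."""


class UndefinedMetricError(InputError):
    """A metric is undefined for the given data (zero variance, zero measured)."""
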