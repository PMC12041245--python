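"""Exception hierarchy for cociteembed.

Every error raised by the library derives from :class:`CociteError`, so
callers (and the CLI) can catch one base class. The subclasses mirror the
failure modes of the pipeline stages: bad configuration, malformed inputs,
routing misses, infeasible sampling requests and incomplete run state.
"""


class CociteError(Exception):
    """Base class for all cociteembed errors."""


class ConfigError(CociteError, ValueError):
    """Invalid configuration values (counts < 1, fractions out of range...)."""


class InputError(CociteError, ValueError):
    """Malformed runtime input (out-of-vocabulary ids, all-masked pooling...)."""


class ArgumentError(CociteError, ValueError):
    """Invalid argument to an operation (sample size too large, b < 2...)."""


class DataError(CociteError, ValueError):
    """Referential problems in data (missing record ids, empty domain corpus)."""


class RoutingError(CociteError, LookupError):
    """A domain label with no registered token or expert. No silent fallback."""


class SurgeryError(CociteError, ValueError):
    """Mixture-of-experts extension cannot be performed on this model."""


class InfeasibleError(CociteError, ValueError):
    """A sampling request that cannot be satisfied (too few eligible pairs)."""


class UndefinedRatioError(CociteError, ArithmeticError):
    """Positive/negative similarity ratio undefined (non-positive negative mean)."""


class StateError(CociteError, RuntimeError):
    """An operation on an incomplete or inconsistent run directory."""
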