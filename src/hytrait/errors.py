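"""Exception hierarchy for hytrait."""


class HytraitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HytraitError):
    """A configuration file or argument set is incomplete or inconsistent."""


class ValidationError(HytraitError):
    """An input value violates a documented precondition."""


class NumericalError(HytraitError):
    """A numerical routine failed beyond recoverable tolerance (e.g. a
    covariance factorization that stays indefinite after jitter escalation)."""
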