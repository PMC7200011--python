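"""Exception hierarchy shared across the package."""


class EnvnetError(Exception):
    """Base class for all package errors."""


class ValidationError(EnvnetError):
    """Input fails a structural invariant (shape, emptiness, value domain)."""


class FormatError(EnvnetError):
    """A file does not parse in the declared dialect."""


class ParameterError(EnvnetError):
    """A parameter is outside its admissible range."""


class GenerationError(EnvnetError):
    """A stochastic generator exhausted its attempt budget."""


class UndefinedMetricError(EnvnetError):
    """A metric is undefined for this input (e.g. λ2 = 0 for a rank-1 matrix)."""
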