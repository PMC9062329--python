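"""Exception hierarchy shared across the package."""


class EqtlDesignError(Exception):
    """Base class for all package errors."""


class ParameterError(EqtlDesignError, ValueError):
    """A parameter is outside its valid domain."""


class ConsistencyError(EqtlDesignError, ValueError):
    """Two inputs that must agree (gene sets, sample sets, ids) do not."""


class StatisticError(EqtlDesignError, ValueError):
    """A statistic is undefined for the given input (e.g. too few samples)."""


class FitError(EqtlDesignError, RuntimeError):
    """A model fit cannot be performed on the given points."""


class DependencyError(EqtlDesignError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""
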