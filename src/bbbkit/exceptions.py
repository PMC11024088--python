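"""Exception hierarchy for bbbkit."""


class BBBKitError(Exception):
    """Base class for all bbbkit errors."""


class InputError(BBBKitError):
    """Invalid user-supplied data (bad columns, malformed vectors, ...)."""


class ConfigurationError(BBBKitError):
    """Invalid or unsatisfiable configuration (missing backend, bad option)."""


class ScoringError(BBBKitError):
    """A descriptor cannot be scored (e.g. a class has no usable values)."""


class UndefinedMetricError(BBBKitError):
    """A performance metric is mathematically undefined for the given input.

    Carries a human-readable reason naming the zero margin.
    """

    def __init__(self, metric: str, reason: str):
        self.metric = metric
        self.reason = reason
        super().__init__(f"{metric} undefined: {reason}")
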