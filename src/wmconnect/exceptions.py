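"""Exception hierarchy for the wmconnect pipeline."""


class WMConnectError(Exception):
    """Base class for all wmconnect errors."""


class ValidationError(WMConnectError):
    """An on-disk artifact or in-memory object violates a structural invariant."""


class ConfigError(WMConnectError):
    """A configuration value is outside its admissible range."""


class SimulationError(WMConnectError):
    """The synthetic-cohort generator produced an unusable network."""


class EmptyRangeError(WMConnectError):
    """No sparsity level satisfies the network-selection criteria.

    Carries per-criterion diagnostics in ``diagnostics`` (a DataFrame with one
    row per candidate sparsity).
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
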