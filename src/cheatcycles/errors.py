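"""Exception hierarchy."""


class CheatCyclesError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CheatCyclesError, ValueError):
    """A model, passage, or metapopulation parameter violates its bounds."""


class DomainError(CheatCyclesError, ValueError):
    """A function argument is outside its mathematical domain."""


class IntegrationError(CheatCyclesError, RuntimeError):
    """The ODE solver failed; the message carries solver diagnostics."""


class ConfigError(CheatCyclesError, ValueError):
    """A run configuration is invalid; the message names the offending key."""
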