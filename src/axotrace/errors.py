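"""Exception hierarchy."""


class AxotraceError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AxotraceError):
    """Invalid parameter, gate id or configuration value."""


class SolverError(AxotraceError):
    """Numerical failure: resting-state non-convergence, non-finite state."""


class ProtocolError(AxotraceError):
    """A threshold-tracking protocol could not be completed."""


class InexcitableError(ProtocolError):
    """No action potential even at the upper stimulus search bound."""


class SpontaneousActivityError(ProtocolError):
    """An action potential occurs with zero test-stimulus amplitude."""


class SchemaError(AxotraceError):
    """Malformed tabular input (missing columns, bad values); carries line info."""


class SequenceError(AxotraceError):
    """A von Frey response sequence violates the up-down rule."""
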