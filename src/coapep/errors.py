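"""Exception hierarchy shared across the package."""


class CoapepError(Exception):
    """Base class for all package-specific errors."""


class InputError(CoapepError, ValueError):
    """Malformed user input (bad sequence, bad file, wrong length)."""


class ConfigurationError(CoapepError, ValueError):
    """Invalid or infeasible parameter/configuration values."""


class StateError(CoapepError, RuntimeError):
    """An object is not in a state that permits the requested operation."""


class MoveError(CoapepError, RuntimeError):
    """No legal Monte Carlo move could be generated within the retry budget."""


class AnalysisError(CoapepError, RuntimeError):
    """Degenerate geometry or data that cannot be analyzed."""
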