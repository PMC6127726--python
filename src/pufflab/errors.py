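"""Exception hierarchy."""


class PufflabError(Exception):
    """Base class for all package errors."""


class ValidationError(PufflabError, ValueError):
    """Invalid argument or inconsistent input data."""


class SimulationError(PufflabError, RuntimeError):
    """Simulator could not satisfy the requested configuration."""
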