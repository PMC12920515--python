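"""Exception types shared across the pipeline."""


class EnvTRFError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(EnvTRFError, ValueError):
    """A configuration value is out of its valid range."""


class InvalidInputError(EnvTRFError, ValueError):
    """An input signal or array violates a precondition."""


class DegenerateInputError(EnvTRFError, ValueError):
    """Input is formally valid but numerically degenerate (e.g. zero variance)."""
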