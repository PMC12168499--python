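"""Exception hierarchy shared across the package."""


class PerturbscopeError(Exception):
    """Base class for all package errors."""


class ConfigError(PerturbscopeError):
    """Invalid configuration; the message names the offending field."""


class FormatError(PerturbscopeError):
    """Malformed input file; the message carries line context when known."""


class ValidationError(PerturbscopeError):
    """Inputs violate a documented invariant."""


class PipelineError(PerturbscopeError):
    """A pipeline stage failed; the message names the stage."""
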