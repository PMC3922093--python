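"""Exception types shared across the pipeline."""


class ImmunosigError(Exception):
    """Base class for all package errors."""


class ConfigError(ImmunosigError, ValueError):
    """Invalid configuration; the message names the violated field."""


class ValidationError(ImmunosigError, ValueError):
    """Invalid data passed to an operation."""


class ParseError(ImmunosigError, ValueError):
    """Malformed input file; the message carries the line number."""


class ReconstructionError(ImmunosigError, RuntimeError):
    """No consistent, or no unique, parameter pair for a printed table."""


class PipelineError(ImmunosigError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
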