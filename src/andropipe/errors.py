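"""Exception types shared across the pipeline stages."""


class AndropipeError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(AndropipeError, ValueError):
    """A configuration value is out of range or names an unknown entity."""


class InvalidInputError(AndropipeError, ValueError):
    """An input value violates an operation's preconditions."""


class InvalidDesignError(AndropipeError, ValueError):
    """The experimental design is unusable (e.g. a group with <2 samples)."""


class DegenerateInputError(AndropipeError, ValueError):
    """Numerically degenerate input (non-positive signal where positivity is required)."""


class ParseError(AndropipeError, ValueError):
    """A flat file could not be parsed; the message carries the line number."""


class PipelineStageError(AndropipeError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
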