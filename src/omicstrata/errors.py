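"""Exception hierarchy used across the pipeline."""


class OmicstrataError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(OmicstrataError, ValueError):
    """A configuration object violates its invariants."""


class InvalidInputError(OmicstrataError, ValueError):
    """Input data violates an operation precondition."""


class MalformedRecordError(OmicstrataError, ValueError):
    """A single input record is structurally broken (bad segment, missing field)."""


class EmptyResultError(OmicstrataError, RuntimeError):
    """A filtering step removed everything; carries a diagnostic message."""


class NoSolutionError(OmicstrataError, RuntimeError):
    """A selection step found no admissible candidate."""


class DependencyError(OmicstrataError, RuntimeError):
    """A pipeline stage is enabled but its upstream output is missing."""
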