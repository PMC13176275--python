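"""Exception hierarchy shared by all stages."""


class StressComboError(Exception):
    """Base class for package errors."""


class ConfigurationError(StressComboError):
    """Invalid scenario/run configuration (bad levels, replicates, constants)."""


class DomainError(StressComboError, ValueError):
    """A measurement is outside the physically meaningful domain."""


class InputError(StressComboError, ValueError):
    """Malformed input table: missing columns, missing groups, unbalanced design."""


class GenerationError(StressComboError):
    """The synthetic generator could not produce admissible values."""


class PipelineError(StressComboError):
    """A pipeline stage failed; the message names the stage."""
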