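"""Exception hierarchy shared across the pipeline stages."""


class LncMetaError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(LncMetaError):
    """Invalid simulation or pipeline configuration."""


class MappingError(LncMetaError):
    """Transcript-to-gene mapping failure (unmapped transcripts)."""


class NormalizationError(LncMetaError):
    """Normalization cannot proceed (e.g. an all-zero sample)."""


class InsufficientStudiesError(LncMetaError):
    """A meta-analytic statistic requires at least two studies."""


class InputError(LncMetaError):
    """Malformed numeric input to a statistical routine."""


class PipelineError(LncMetaError):
    """A pipeline stage failed; the message names the stage."""
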