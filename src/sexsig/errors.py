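"""Exception hierarchy shared across the pipeline."""


class SexsigError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SexsigError):
    """A file does not conform to its declared dialect (bad header, wrong
    dimensions, unparseable values)."""


class ValidationError(SexsigError):
    """An in-memory object violates a contract (duplicate ids, out-of-range
    thresholds, inconsistent counts)."""


class VocabularyError(ValidationError):
    """A categorical token falls outside its closed vocabulary."""


class PipelineError(SexsigError):
    """A pipeline stage failed; the message names the stage."""
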