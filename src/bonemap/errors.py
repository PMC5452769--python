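"""Exception hierarchy shared across the pipeline."""


class BonemapError(Exception):
    """Base class for all package errors."""


class ValidationError(BonemapError, ValueError):
    """Bad inputs or configuration (CLI exit code 2)."""


class ProcessingError(BonemapError, RuntimeError):
    """A pipeline stage failed on otherwise valid inputs (CLI exit code 3)."""
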