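"""Exception hierarchy shared across the package."""


class DemetaError(Exception):
    """Base class for all package errors."""


class ValidationError(DemetaError, ValueError):
    """Invalid user input: malformed files, inconsistent metadata, bad parameters."""


class StudyRejectionError(ValidationError):
    """A study fails the inclusion rules (e.g. a contrast group with fewer than 2 samples)."""


class PipelineError(DemetaError):
    """A pipeline stage aborted; the message names the stage and the offending entity."""
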