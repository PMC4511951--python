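"""Exception hierarchy shared across the package."""


class FfpeqcError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FfpeqcError):
    """Invalid simulation or run configuration."""


class GenerationError(FfpeqcError):
    """Synthetic-data generation cannot satisfy the requested configuration."""


class ClassificationError(FfpeqcError):
    """A read or variant could not be classified (e.g. unknown chromosome)."""


class ValidationError(FfpeqcError):
    """Malformed input records or impossible values."""


class StageError(FfpeqcError):
    """A pipeline stage failed; dependents are aborted."""
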