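"""Exception hierarchy shared across the pipeline."""


class DistexpError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DistexpError):
    """A trial table or config does not match the expected schema."""


class FormatError(DistexpError):
    """A serialized container is missing pieces (e.g. the JSON sidecar)."""


class IntegrityError(DistexpError):
    """A serialized container is internally inconsistent."""


class ChannelError(DistexpError):
    """A required channel is absent from the montage/data."""


class ParameterError(DistexpError):
    """An analysis parameter is out of range (cutoffs, windows, bands)."""


class ConfigError(DistexpError):
    """A simulation or pipeline configuration is invalid."""


class InsufficientDataError(DistexpError):
    """Too few trials/subjects for the requested operation."""


class LeakageError(DistexpError):
    """Train and test sets share trials."""


class DependencyError(DistexpError):
    """A pipeline stage is missing an upstream artifact."""
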