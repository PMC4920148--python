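"""Exception hierarchy shared across the package.

Validation problems (malformed files, inconsistent configuration) derive from
:class:`ValidationError` so the CLI can map them to exit code 2, distinct from
runtime failures (exit code 1).
"""


class HTSError(Exception):
    """Base class for all package errors."""


class ValidationError(HTSError, ValueError):
    """Invalid user input: malformed file, bad configuration, bad parameter."""


class LayoutError(ValidationError):
    """Plate-layout file violates the layout contract."""


class MeasurementError(ValidationError):
    """Measurement table violates the dataset contract."""


class ConfigError(ValidationError):
    """Inconsistent or unknown configuration keys/values."""


class PlateError(HTSError):
    """A plate (or plate run) cannot be normalized, e.g. no usable vehicle wells."""


class PipelineError(HTSError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
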