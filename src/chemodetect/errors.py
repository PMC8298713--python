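"""Exception hierarchy used across the package."""


class ChemodetectError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChemodetectError, ValueError):
    """An input table violates the expected file format."""


class ConsistencyError(ChemodetectError, ValueError):
    """Logically inconsistent observation data (duplicate detections,
    class labels changing within one cell track, ...)."""


class DegenerateCellError(ChemodetectError, ValueError):
    """A cell's track carries no usable motion (e.g. all step widths zero)."""


class ConfigurationError(ChemodetectError, ValueError):
    """Analysis objects were combined with mismatched settings."""


class InsufficientDataError(ChemodetectError, RuntimeError):
    """No triplets or immune-target pairs survive the configured filters."""
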