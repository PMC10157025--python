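"""Exception hierarchy shared across the package."""


class WmiusError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(WmiusError):
    """Invalid configuration value or degenerate parameter combination."""


class FormatError(WmiusError):
    """Malformed on-disk artifact (manifest header, mask encoding, ...)."""


class ConsistencyError(WmiusError):
    """Data violates an internal invariant (e.g. one subject, two labels)."""


class RoiError(WmiusError):
    """Empty or otherwise unusable region of interest."""


class DegenerateLabelError(WmiusError):
    """An operation requiring both classes received a single-class vector."""


class ShapeError(WmiusError):
    """Array shapes are incompatible."""
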