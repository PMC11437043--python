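"""Exception types shared across the package."""


class WingAsymError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(WingAsymError, ValueError):
    """An input violates a documented precondition."""


class ImageIOError(WingAsymError, IOError):
    """A raster file could not be read or written."""
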