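"""Typed exceptions shared across the package."""


class AdipomorphError(Exception):
    """Base class for all package errors."""


class ImageIOError(AdipomorphError):
    """A file could not be read or written as an image/label map."""


class MissingPixelSizeError(ImageIOError):
    """No pixel size was supplied and none is embedded in the file."""


class LabelDTypeError(ImageIOError):
    """A label-map file does not contain non-negative integers."""


class PlacementError(AdipomorphError):
    """Synthetic droplets could not be placed without overlap."""


class ValidationError(AdipomorphError):
    """An input violates a documented precondition."""
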