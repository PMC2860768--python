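"""Exception hierarchy shared across the pipeline stages."""


class QLFError(Exception):
    """Base class for all package errors."""


class ImageFormatError(QLFError):
    """The input image is not a grayscale 8/16-bit PNG or TIFF."""


class ImageIOError(QLFError):
    """The image file could not be read or written."""


class GeometryError(QLFError):
    """The polygon ROI is invalid (self-intersecting, empty interior, ...)."""


class BoundsError(GeometryError):
    """The polygon ROI does not fit inside the image."""


class ConsistencyError(QLFError):
    """Two pipeline objects (image / raster / loss map) do not match in shape."""


class ParameterError(QLFError):
    """A numeric parameter is outside its documented range."""


class EmptyLesionError(QLFError):
    """A loss map contains no valid interior pixel."""


class CalibrationError(QLFError):
    """The calibration data or fitted model cannot be used."""
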