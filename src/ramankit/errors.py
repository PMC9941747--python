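"""Exception hierarchy shared across the package."""


class RamanKitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RamanKitError, ValueError):
    """A file does not conform to the expected spectrum schema."""


class DimensionError(RamanKitError, ValueError):
    """Vector/matrix shapes are incompatible."""


class CalibrationError(RamanKitError, RuntimeError):
    """Axis calibration could not be established."""


class RangeError(RamanKitError, ValueError):
    """A requested range falls outside the valid domain."""
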