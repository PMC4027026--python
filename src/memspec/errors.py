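"""Exception hierarchy.

All package errors derive from :class:`MemspecError` so callers can catch
one base class; most also derive from the closest builtin (ValueError /
OSError) so generic code behaves sensibly.
"""


class MemspecError(Exception):
    """Base class for all memspec errors."""


class ParseError(MemspecError, ValueError):
    """A spectrum or table file could not be parsed; message names the line."""


class SizeError(MemspecError, ValueError):
    """Input has too few points for the requested operation."""


class AxisError(MemspecError, ValueError):
    """Abscissa is not strictly monotonic, or a value lies outside it."""


class UnitError(MemspecError, ValueError):
    """Wrong or unsupported axis unit for the requested operation."""


class UnitConversionError(UnitError):
    """Requested axis conversion is not defined (e.g. Gauss -> ppm)."""


class RangeError(MemspecError, ValueError):
    """Axis does not cover the frequency range the operation needs."""


class DegenerateInputError(MemspecError, ValueError):
    """Input carries no usable signal (e.g. an all-zero spectrum)."""


class MeasurementError(MemspecError, ValueError):
    """A spectral measurement could not be taken (no edges, too few extrema)."""


class NonIdentifiableError(MemspecError, ValueError):
    """Fit requested on data that cannot constrain the parameters."""


class AssignmentError(MemspecError, ValueError):
    """Chain-position assignment impossible (too few splittings)."""


class AlignmentError(MemspecError, ValueError):
    """Two profiles do not share the position labels needed for comparison."""


class ConfigError(MemspecError, ValueError):
    """Pipeline configuration is invalid; message lists offending fields."""
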