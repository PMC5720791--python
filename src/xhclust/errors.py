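"""Exception hierarchy for xhclust.

All library errors derive from :class:`XhclustError` so callers can catch
one base class; specific subclasses mark the contract that was violated.
"""


class XhclustError(Exception):
    """Base class for all xhclust errors."""


class FormatError(XhclustError):
    """A file does not conform to the expected format (e.g. an ENVI header
    without a wavelength list)."""


class CorruptFileError(XhclustError):
    """Header metadata and payload disagree (band count, payload size)."""


class CalibrationError(XhclustError):
    """White/dark references are unusable (white - dark <= 0 in a band)."""


class ParameterError(XhclustError):
    """A parameter violates its contract (window too long, empty crop, ...)."""


class ConsistencyError(XhclustError):
    """Internally inconsistent inputs (pixel index out of bounds, duplicate
    back-map entries, mismatched shapes)."""


class DegenerateNodeError(XhclustError):
    """All points in a node coincide; the caller should make it a leaf."""


class DegenerateSplitError(XhclustError):
    """All projection values are equal; no split point exists."""


class GenerationError(XhclustError):
    """The synthetic-scene generator could not satisfy its constraints."""
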