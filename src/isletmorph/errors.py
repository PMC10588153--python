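"""Exception hierarchy for isletmorph.

All errors derive from :class:`IsletMorphError` so callers can catch the
package's failures with a single ``except`` clause; each subclass also
derives from the closest built-in (``ValueError`` / ``KeyError``) so that
generic error handling keeps working.
"""


class IsletMorphError(Exception):
    """Base class for all isletmorph errors."""


class InvalidGeometryError(IsletMorphError, ValueError):
    """Polygon is degenerate, self-intersecting, or otherwise unusable."""


class DomainError(IsletMorphError, ValueError):
    """A numeric argument lies outside the mathematically valid domain."""


class LabelNotFoundError(IsletMorphError, KeyError):
    """Requested label is absent from a label mask."""


class NoForegroundError(IsletMorphError, ValueError):
    """Automatic thresholding found no foreground (e.g. constant image)."""


class ZeroAreaError(IsletMorphError, ValueError):
    """A tissue mask is empty, so area-normalised densities are undefined."""


class DegenerateDataError(IsletMorphError, ValueError):
    """Inputs leave a test statistic undefined (e.g. zero pooled variance
    with unequal means)."""


class InsufficientDataError(IsletMorphError, ValueError):
    """Fewer observations than the statistic requires."""


class IncompleteSheetError(IsletMorphError, KeyError):
    """A rater answer sheet does not cover every presented slide."""


class CanvasTooSmallError(IsletMorphError, ValueError):
    """Islet polygons could not be packed into the rendered tissue region."""
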