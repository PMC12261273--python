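"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`AptadynError`
so callers (and the CLI) can catch one type.
"""


class AptadynError(Exception):
    """Base class for all package errors."""


class FormatError(AptadynError):
    """A file does not conform to its declared format."""


class EmptyInputError(AptadynError):
    """An input that must contain data is empty."""


class TopologyValidationError(AptadynError):
    """A topology violates its invariants (missing parameters, duplicates...)."""


class SelectionError(AptadynError):
    """An atom mask resolved to an empty or invalid selection."""


class GeometryError(AptadynError):
    """A geometric operation received degenerate input (collinear, <3 atoms...)."""


class DegenerateInputError(AptadynError):
    """An estimator received input it cannot meaningfully process (e.g. one frame)."""


class ParseError(AptadynError):
    """Secondary-structure text could not be parsed."""


class StructureValidationError(AptadynError):
    """A secondary structure violates its invariants (conflicts, pseudoknots)."""


class ParameterCoverageError(AptadynError):
    """An energy-parameter table lacks an entry for an encountered motif."""


class CoverageError(AptadynError):
    """All histogram bins were masked; no free-energy estimate is possible."""


class AlignmentError(AptadynError):
    """Two sequence variants could not be index-aligned."""


class DependencyError(AptadynError):
    """A pipeline stage is missing an artifact a previous stage should provide."""
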