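"""Exception hierarchy.

Every error raised on a per-region basis (seed not found, degenerate motif,
zero mapped units ...) derives from :class:`RegionError`, so the pipeline can
demote a single candidate region without aborting the whole record.
"""


class PeriscanError(Exception):
    """Base class for all periscan errors."""


class InputError(PeriscanError):
    """Unreadable or unparsable input file."""


class EmptyInputError(InputError):
    """An input file that parses but contains zero sequence entries."""


class ValidationError(PeriscanError):
    """An argument violates a documented precondition."""


class RegionError(PeriscanError):
    """Base class for failures local to one candidate region."""


class EmptyTrackError(RegionError):
    """Sequence shorter than the k-mer size; no score track can be built."""


class EmptyMatrixError(RegionError):
    """Scanned region too short to build a position-period matrix."""


class NoPeriodError(RegionError):
    """Position-period matrix carries no mass; no dominant period exists."""


class UndefinedScoreError(RegionError):
    """Periodicity score denominator is zero."""


class SeedNotFoundError(RegionError):
    """No k-mer recurs at a distance near the dominant period."""


class InsufficientUnitsError(RegionError):
    """Fewer than two seed occurrences; units cannot be extracted."""


class AlignmentError(RegionError):
    """Multiple-alignment backend failure."""


class DegenerateMotifError(RegionError):
    """Punctuation removed every alignment column."""


class MappingError(RegionError):
    """The representative motif mapped to zero units in the region."""
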