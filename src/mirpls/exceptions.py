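"""Exception hierarchy for mirpls.

Every error raised by the library derives from :class:`MirplsError` so
callers can catch the whole family with one clause.
"""


class MirplsError(Exception):
    """Base class for all mirpls errors."""


class SpectraParseError(MirplsError):
    """A spectra file could not be parsed (bad cell, missing header, ...)."""


class GridError(MirplsError):
    """Wavenumber grid violates an invariant (non-monotonic, non-uniform)."""


class RegionError(MirplsError):
    """Requested spectral region does not intersect the grid."""


class IdentityError(MirplsError):
    """Duplicate or inconsistent sample identifiers."""


class FormatError(MirplsError):
    """A JCAMP-DX (or other structured) file is malformed or truncated."""


class PipelineError(MirplsError):
    """Unknown pre-treatment name or invalid step configuration."""


class DegenerateSpectrumError(MirplsError):
    """A spectrum is flat where a non-zero range is required."""


class StateError(MirplsError):
    """A fitted-state operation was used before fitting."""


class RankError(MirplsError):
    """Requested model complexity exceeds the rank the data supports."""


class DegenerateDataError(MirplsError):
    """Response or design has no variance where variance is required."""


class DomainError(MirplsError):
    """Scalar argument outside its physical domain (e.g. spike added <= 0)."""
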