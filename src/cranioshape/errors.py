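"""Exception hierarchy for cranioshape."""


class CranioshapeError(Exception):
    """Base class for all cranioshape errors."""


class FormatError(CranioshapeError):
    """A file could not be read or written in a supported volume format."""


class DimensionalityError(CranioshapeError):
    """A volume payload is not three-dimensional."""


class GridMismatchError(CranioshapeError):
    """Two volumes that must share a grid (shape + spacing) do not."""


class DegenerateInputError(CranioshapeError):
    """An operation received an input it cannot act on (e.g. empty mask)."""


class PoolSizeError(CranioshapeError):
    """A shape pool has too few members to build a model."""


class PhantomSpecError(CranioshapeError):
    """A synthetic phantom or defect specification is geometrically invalid."""
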