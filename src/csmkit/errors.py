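"""Exception types raised across the package."""


class CSMError(Exception):
    """Base class for all csmkit errors."""


class PDBFormatError(CSMError):
    """The input could not be parsed as PDB-format text."""


class EmptyStructureError(CSMError):
    """A structure yielded zero extractable residue centroids."""


class IdentifierCollisionError(CSMError):
    """Duplicate structure identifiers where uniqueness is required."""


class SchemaError(CSMError):
    """A label table is malformed (missing id column, bad EC string, ...)."""


class EmptyDatasetError(CSMError):
    """A filtering or selection step removed every row."""


class NoElbowError(CSMError):
    """Automatic rank selection found no drop in the singular-value spectrum."""


class RankError(CSMError):
    """Requested SVD rank is outside [1, p]."""


class StratificationError(CSMError):
    """A class has fewer members than the number of cross-validation folds."""


class ComparisonError(CSMError):
    """Two metric reports cover different class sets."""
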