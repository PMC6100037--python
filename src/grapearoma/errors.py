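"""Exception hierarchy shared across the package."""


class GrapeAromaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GrapeAromaError, ValueError):
    """An input table is structurally malformed (missing columns, empty file)."""


class ValidationError(GrapeAromaError, ValueError):
    """A value violates a domain invariant (negative concentration, bad class, ...)."""


class ReferenceError_(GrapeAromaError, KeyError):
    """A record refers to an entity that does not exist (unknown compound, sample)."""


class TaxonomyError(GrapeAromaError, ValueError):
    """The aromatic-series taxonomy is internally inconsistent."""


class ModelError(GrapeAromaError, ValueError):
    """A chemometric model cannot be fitted or applied as requested."""
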