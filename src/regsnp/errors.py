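"""Exception hierarchy shared across the pipeline."""


class RegsnpError(Exception):
    """Base class for all pipeline errors."""


class FormatError(RegsnpError):
    """A file does not conform to its declared format."""


class UndefinedLdError(RegsnpError):
    """LD is undefined (monomorphic site / zero allele-frequency margin)."""


class InsufficientDataError(RegsnpError):
    """Too few informative observations to estimate the quantity."""


class ReferenceMismatchError(RegsnpError):
    """A variant's REF allele disagrees with the reference sequence."""


class BoundaryError(RegsnpError):
    """A requested window runs off the end of a contig."""


class InputError(RegsnpError):
    """Invalid or degenerate user input to an operation."""


class UndefinedAssociationError(RegsnpError):
    """Association is undefined (e.g. constant genotype dosage)."""


class FeasibilityError(RegsnpError):
    """Requested simulation parameters are jointly infeasible."""
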