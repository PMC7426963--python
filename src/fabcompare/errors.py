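"""Exception hierarchy for the Fab comparison pipeline.

Every failure mode that corresponds to a selection filter or a validation
rule gets its own class so callers (and the batch driver) can react to the
reason, not the message.
"""


class FabCompareError(Exception):
    """Base class for all package errors."""


class ParseError(FabCompareError):
    """The PDB text could not be interpreted (no ATOM records, bad coords)."""


class MissingChainError(FabCompareError):
    """Requested chain id is not present in the structure."""


class DiscontinuityError(FabCompareError):
    """A chain has a broken backbone (C(i)-N(i+1) beyond the bond cutoff)."""


class ResolutionError(FabCompareError):
    """A structure fails the crystallographic resolution filter."""


class SpanError(FabCompareError):
    """A residue span is invalid for the chain or region it must lie in."""


class ShapeError(FabCompareError):
    """Coordinate arrays have mismatched or invalid shapes."""


class DegenerateError(FabCompareError):
    """Geometry is degenerate (coincident/collinear points)."""


class EmptySpanError(FabCompareError):
    """A requested region contains no scored residues."""


class AnchorNotFoundError(FabCompareError):
    """A conserved anchor residue could not be located in its region."""


class AnchorIdentityError(FabCompareError):
    """An anchor override points at a residue of the wrong amino-acid type."""


class AnchorMismatchError(FabCompareError):
    """Free and bound forms use different anchor positions."""


class PairingError(FabCompareError):
    """Free and bound chains do not share 100% sequence identity."""


class SpecError(FabCompareError):
    """A synthetic-structure specification is invalid."""


class FetchError(FabCompareError):
    """A PDB entry could not be retrieved from the RCSB."""
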