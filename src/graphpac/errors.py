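"""Exception types shared across the pipeline."""


class GraphPACError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(GraphPACError):
    """A malformed ATOM record (the message names the offending line)."""


class EmptyChainError(GraphPACError):
    """The requested chain contains no atoms of the configured name."""


class SchemaError(GraphPACError):
    """A mutation table is missing a required column."""


class RowError(GraphPACError):
    """A mutation table row could not be parsed (message carries the line number)."""


class AlignmentError(GraphPACError):
    """Pairwise alignment below the identity threshold, or otherwise unusable."""


class InsufficientMutationsError(GraphPACError):
    """Fewer than two mutations remain on residues with coordinates.

    Structures raising this are dropped from a batch run: with zero or one
    mutation there is no pair of order statistics to test.
    """
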