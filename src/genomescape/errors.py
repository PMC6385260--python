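"""Typed exceptions shared across the package."""


class GenomescapeError(Exception):
    """Base class for all package errors."""


class AlphabetMismatchError(GenomescapeError):
    """Two sequences with incompatible alphabets were combined."""


class EmptySequenceError(GenomescapeError):
    """A sequence (or sequence set) that must be non-empty was empty."""


class DegenerateAlignmentError(GenomescapeError):
    """Filtering left an alignment with <2 rows or 0 columns."""


class TaxonSetMismatchError(GenomescapeError):
    """Alignments to be concatenated do not share one taxon set."""


class InvalidTreeError(GenomescapeError):
    """A distance matrix or tree violated its preconditions."""


class InvalidCoverageError(GenomescapeError):
    """Coverage must be strictly positive."""


class EmptyInputError(GenomescapeError):
    """An operation requiring at least one record received none."""


class DuplicateIdError(GenomescapeError):
    """Identifiers must be unique within an input set."""


class MissingCompletenessError(GenomescapeError):
    """A 1:1 merge decision needs completeness on both models."""


class UndefinedFoldError(GenomescapeError):
    """Fold change is undefined when the denominator count is zero."""


class SpeciesMismatchError(GenomescapeError):
    """A clade partition names species absent from the family counts."""


class CoordinateError(GenomescapeError):
    """A feature lies outside its contig or has inverted coordinates."""


class DegenerateInputError(GenomescapeError):
    """Statistical input was constant where variation is required."""


class QueryNotInTreeError(GenomescapeError):
    """The focal query leaf is absent from the gene tree."""


class MultiContigError(GenomescapeError):
    """Candidate genes must be colinear on a single contig."""


class MissingGeneError(GenomescapeError):
    """A requested gene id is absent from the expression matrix."""


class TranslationMismatchError(GenomescapeError):
    """A CDS does not translate to its claimed protein row."""


class PartialCodonGapError(GenomescapeError):
    """Gaps in a codon alignment must come in whole-codon units."""


class InternalStopError(GenomescapeError):
    """An in-frame stop codon occurred inside a coding sequence."""


class InvalidPValueError(GenomescapeError):
    """P-values must lie in (0, 1]."""


class InfeasiblePackingError(GenomescapeError):
    """Requested gene/repeat content does not fit the contig lengths."""
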