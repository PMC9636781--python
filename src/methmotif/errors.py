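"""Exception hierarchy for methmotif.

Every anticipated failure mode raises a distinct, named subclass of
:class:`MethMotifError` so callers can catch precisely what they expect.
"""


class MethMotifError(Exception):
    """Base class for all methmotif errors."""


class EmptyFastaError(MethMotifError):
    """FASTA file contained no records."""


class DuplicateContigError(MethMotifError):
    """Two FASTA records share a contig name."""


class MalformedRecordError(MethMotifError):
    """A cytosine-report line failed to parse; message names the line."""


class OverlappingBinsError(MethMotifError):
    """Bins of a track overlap within a contig."""


class InvalidAnchorError(MethMotifError):
    """A BED anchor interval is invalid (start >= end, bad strand)."""


class InvalidMotifError(MethMotifError):
    """A motif string is not valid IUPAC, or its target offset is not a C."""


class CoordinateError(MethMotifError):
    """A record's coordinates fall outside its contig, or the referenced
    base is not a cytosine on the stated strand."""


class EmptyInputError(MethMotifError):
    """An operation requiring at least one element received none."""


class DegenerateLogoError(MethMotifError):
    """Every position of the logo is degenerate (no methylation signal)."""
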