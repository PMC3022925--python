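"""Exception hierarchy for the snpchar pipeline.

Every error raised by the package derives from :class:`SnpCharError`, so
callers can catch pipeline failures without catching programming errors.
"""


class SnpCharError(Exception):
    """Base class for all snpchar errors."""


class ParseError(SnpCharError):
    """A file could not be parsed (malformed FASTA/TSV/VCF/Stockholm)."""


class DuplicateIdError(SnpCharError):
    """Two records in one input share an identifier that must be unique."""


class ValidationError(SnpCharError):
    """A record violates a domain invariant (e.g. ref base equals alt base)."""


class RangeError(SnpCharError):
    """A coordinate falls outside the sequence or alignment it refers to."""


class LengthMismatchError(SnpCharError):
    """Alignment rows are ragged (unequal aligned lengths)."""


class LookupError_(SnpCharError):
    """A referenced identifier (gene, alignment row) is not present."""


class FrameError(SnpCharError):
    """An ORF length is not a positive multiple of three."""


class RefBaseMismatchError(SnpCharError):
    """The ORF base at a SNP position differs from the SNP's stated ref base."""


class IndeterminateCodonError(SnpCharError):
    """The codon affected by a SNP contains an 'N' and cannot be translated."""


class EmptyColumnError(SnpCharError):
    """An alignment column holds no ungapped residues among the counted rows."""


class EmptyInputError(SnpCharError):
    """An operation requiring a non-empty input received an empty one."""


class MembershipError(SnpCharError):
    """A gene id is missing from the declared universe or considered set."""


class ConfigError(SnpCharError):
    """A simulation or threshold configuration is internally inconsistent."""


class CapacityError(SnpCharError):
    """An ORF is too short to host the requested number of distinct SNPs."""
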