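"""Core record types and readers/writers for every external format.

Coordinates are 1-based and ORF-relative on the coding strand throughout the
package. Sequences are DNA over {A,C,G,T,N}; 'U' is rejected. Alignment gap
characters are normalized to '-' ('.' accepted on read).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DuplicateIdError,
    LengthMismatchError,
    LookupError_,
    ParseError,
    RangeError,
    ValidationError,
)

VALID_DNA = frozenset("ACGTN")
SNP_BASES = frozenset("ACGT")

SNP_TABLE_COLUMNS = ("gene_id", "position", "ref", "alt")


@dataclass(frozen=True)
class OrfSequence:
    """A gene's protein-coding nucleotide sequence.

    The sequence is stored uppercased and restricted to {A,C,G,T,N}.
    """

    gene_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValidationError(f"ORF {self.gene_id!r}: empty sequence")
        bad = set(seq) - VALID_DNA
        if bad:
            raise ValidationError(
                f"ORF {self.gene_id!r}: invalid characters {sorted(bad)!r} "
                "(DNA over A,C,G,T,N expected; 'U' is not accepted)"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SnpRecord:
    """A single-nucleotide substitution at a 1-based position in an ORF."""

    gene_id: str
    position: int
    ref_base: str
    alt_base: str
    strain_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_base", self.ref_base.upper())
        object.__setattr__(self, "alt_base", self.alt_base.upper())
        if self.position < 1:
            raise ValidationError(
                f"SNP {self.gene_id}:{self.position}: position must be >= 1"
            )
        for name, base in (("ref", self.ref_base), ("alt", self.alt_base)):
            if base not in SNP_BASES:
                raise ValidationError(
                    f"SNP {self.gene_id}:{self.position}: {name} base {base!r} "
                    "not a single unambiguous nucleotide"
                )
        if self.ref_base == self.alt_base:
            raise ValidationError(
                f"SNP {self.gene_id}:{self.position}: ref base equals alt base "
                f"({self.ref_base})"
            )

    def validate_against(self, orfs: Mapping[str, OrfSequence]) -> None:
        """Check the record against a loaded ORF set (bounds + known gene)."""
        if self.gene_id not in orfs:
            raise LookupError_(f"SNP references unknown gene {self.gene_id!r}")
        orf = orfs[self.gene_id]
        if self.position > len(orf):
            raise RangeError(
                f"SNP {self.gene_id}:{self.position} beyond ORF length {len(orf)}"
            )


@dataclass(frozen=True)
class HomologAlignmentSet:
    """A per-gene protein multi-alignment: one reference row plus homologues.

    All rows share the aligned length; the gap character is '-'.
    """

    gene_id: str
    reference_row_id: str
    row_ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.rows):
            raise ValidationError("row_ids and rows differ in length")
        if not self.rows:
            raise ValidationError(f"alignment {self.gene_id!r}: no rows")
        length = len(self.rows[0])
        for rid, row in zip(self.row_ids, self.rows):
            if len(row) != length:
                raise LengthMismatchError(
                    f"alignment {self.gene_id!r}: row {rid!r} has length "
                    f"{len(row)}, expected {length}"
                )
        if self.reference_row_id not in self.row_ids:
            raise LookupError_(
                f"alignment {self.gene_id!r}: reference row "
                f"{self.reference_row_id!r} not found"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise DuplicateIdError(
                f"alignment {self.gene_id!r}: duplicate row ids"
            )

    @property
    def aligned_length(self) -> int:
        return len(self.rows[0])

    @property
    def reference_row(self) -> str:
        return self.rows[self.row_ids.index(self.reference_row_id)]

    def homolog_rows(self) -> list[tuple[str, str]]:
        """(row_id, row) pairs for every non-reference row, in file order."""
        return [
            (rid, row)
            for rid, row in zip(self.row_ids, self.rows)
            if rid != self.reference_row_id
        ]


# ---------------------------------------------------------------------------
# ORF FASTA


def read_orf_fasta(path: str | os.PathLike) -> dict[str, OrfSequence]:
    """Read an ORF FASTA file into an id-keyed, insertion-ordered mapping.

    Duplicate ids and non-DNA characters are rejected.
    """
    _precheck_fasta(path)
    orfs: dict[str, OrfSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in orfs:
            raise DuplicateIdError(f"duplicate gene_id {rec.id!r} in {path}")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        orfs[rec.id] = OrfSequence(rec.id, str(rec.seq), desc)
    return orfs


def _precheck_fasta(path: str | os.PathLike) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header '>', "
                    f"found {line.strip()[:30]!r}"
                )
            return  # first non-blank line is a header; hand off to SeqIO


def write_orf_fasta(orfs: Mapping[str, OrfSequence], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(o.sequence), id=o.gene_id, description=o.description)
        for o in orfs.values()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# SNP tables (TSV and VCF-lite)


def read_snp_table(
    path: str | os.PathLike,
    dialect: str = "tsv",
    orfs: Mapping[str, OrfSequence] | None = None,
) -> list[SnpRecord]:
    """Read a SNP table in either the native TSV dialect or VCF-lite.

    TSV: header ``gene_id  position  ref  alt`` (optional ``strain`` column).
    VCF-lite: VCF 4.x body where CHROM is read as the gene id and POS as the
    ORF-relative 1-based position; INFO/FILTER/QUAL are ignored.

    When ``orfs`` is supplied, each record is validated against it
    (known gene, position within the ORF).
    """
    if dialect == "tsv":
        snps = _read_snp_tsv(path)
    elif dialect == "vcf-lite":
        snps = _read_snp_vcf_lite(path)
    else:
        raise ValueError(f"unknown SNP table dialect {dialect!r}")
    if orfs is not None:
        for snp in snps:
            snp.validate_against(orfs)
    return snps


def _read_snp_tsv(path: str | os.PathLike) -> list[SnpRecord]:
    snps: list[SnpRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:4]) != SNP_TABLE_COLUMNS:
            raise ParseError(
                f"{path}: line 1: expected header "
                f"{' '.join(SNP_TABLE_COLUMNS)!r}, found {header!r}"
            )
        has_strain = len(header) > 4 and header[4] == "strain"
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected >=4 columns")
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: position {fields[1]!r} not an integer"
                ) from exc
            strain = fields[4] if has_strain and len(fields) > 4 else ""
            snps.append(SnpRecord(fields[0], pos, fields[2], fields[3], strain))
    return snps


def _read_snp_vcf_lite(path: str | os.PathLike) -> list[SnpRecord]:
    snps: list[SnpRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=5 VCF columns"
                )
            chrom, pos_s, _id, ref, alt = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: POS {pos_s!r} not an integer"
                ) from exc
            snps.append(SnpRecord(chrom, pos, ref, alt))
    return snps


def write_snp_table(snps: Sequence[SnpRecord], path: str | os.PathLike) -> None:
    """Write SNPs in the native TSV dialect (with the strain column)."""
    with open(path, "w") as fh:
        fh.write("\t".join(SNP_TABLE_COLUMNS + ("strain",)) + "\n")
        for s in snps:
            fh.write(
                f"{s.gene_id}\t{s.position}\t{s.ref_base}\t{s.alt_base}"
                f"\t{s.strain_label or '.'}\n"
            )


# ---------------------------------------------------------------------------
# Homologue alignments

_ALIGN_FORMATS = {"aligned-fasta": "fasta", "stockholm": "stockholm"}


def read_alignment(
    path: str | os.PathLike,
    format: str = "aligned-fasta",
    reference_row_id: str | None = None,
    gene_id: str | None = None,
) -> HomologAlignmentSet:
    """Read a protein multi-alignment (aligned FASTA or Stockholm).

    '.' gaps are normalized to '-' and residues uppercased. The reference row
    defaults to the first row when not named. ``gene_id`` defaults to the file
    stem.
    """
    if format not in _ALIGN_FORMATS:
        raise ValueError(f"unknown alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), _ALIGN_FORMATS[format])
    except ValueError as exc:
        # AlignIO refuses ragged inputs for fasta with this message
        if "same length" in str(exc).lower():
            raise LengthMismatchError(f"{path}: {exc}") from exc
        raise ParseError(f"{path}: {exc}") from exc
    row_ids = tuple(rec.id for rec in aln)
    rows = tuple(str(rec.seq).upper().replace(".", "-") for rec in aln)
    if gene_id is None:
        gene_id = os.path.splitext(os.path.basename(str(path)))[0]
    if reference_row_id is None:
        reference_row_id = row_ids[0]
    return HomologAlignmentSet(gene_id, reference_row_id, row_ids, rows)


def write_alignment(
    alignment: HomologAlignmentSet, path: str | os.PathLike,
    format: str = "aligned-fasta",
) -> None:
    if format not in _ALIGN_FORMATS:
        raise ValueError(f"unknown alignment format {format!r}")
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(row), id=rid, description="")
        for rid, row in zip(alignment.row_ids, alignment.rows)
    )
    AlignIO.write(msa, str(path), _ALIGN_FORMATS[format])
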