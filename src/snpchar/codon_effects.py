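"""Codon-level consequence classification for coding SNPs.

Each SNP is mapped to its codon in the frame-1 reading of the supplied ORF,
the reference and variant codons are translated under the standard nuclear
genetic code, and the effect is classified as silent, missense, nonsense
(premature stop gained) or stop-loss. The two-way rollup used in summary
reports counts missense, nonsense and stop-loss together as "nonsynonymous".
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Data import CodonTable

from .errors import (
    FrameError,
    IndeterminateCodonError,
    LookupError_,
    RangeError,
    RefBaseMismatchError,
)
from .io_formats import OrfSequence, SnpRecord

SILENT = "silent"
MISSENSE = "nonsynonymous_missense"
NONSENSE = "nonsynonymous_nonsense"
STOP_LOSS = "stop_loss"
EFFECT_CLASSES = (SILENT, MISSENSE, NONSENSE, STOP_LOSS)

# standard nuclear code, stops mapped to '*'
_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TO_AA.update({codon: "*" for codon in _STANDARD.stop_codons})


def is_nonsynonymous(effect_class: str) -> bool:
    """Two-way rollup: everything that changes the residue, stop included."""
    return effect_class in (MISSENSE, NONSENSE, STOP_LOSS)


@dataclass(frozen=True)
class CodonEffect:
    gene_id: str
    snp_position: int        # 1-based ORF coordinate
    codon_index: int         # 1-based codon number
    codon_offset: int        # 1..3 within the codon
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect_class: str

    @property
    def protein_position(self) -> int:
        """Residue index in the translated protein (equals codon_index)."""
        return self.codon_index


def classify_snp_effect(orf: OrfSequence, snp: SnpRecord) -> CodonEffect:
    """Classify one SNP against its ORF.

    Requires the ORF length to be a multiple of 3 and the ORF base at the SNP
    position to equal the SNP's stated reference base.
    """
    seq = orf.sequence
    if len(seq) % 3 != 0:
        raise FrameError(
            f"ORF {orf.gene_id!r}: length {len(seq)} not a multiple of 3"
        )
    if not 1 <= snp.position <= len(seq):
        raise RangeError(
            f"SNP {snp.gene_id}:{snp.position} outside ORF of length {len(seq)}"
        )
    found = seq[snp.position - 1]
    if found != snp.ref_base:
        raise RefBaseMismatchError(
            f"{snp.gene_id}:{snp.position}: ORF carries {found!r}, "
            f"SNP states ref {snp.ref_base!r}"
        )
    codon_index = (snp.position - 1) // 3 + 1
    offset = (snp.position - 1) % 3 + 1
    start = (codon_index - 1) * 3
    ref_codon = seq[start:start + 3]
    if "N" in ref_codon:
        raise IndeterminateCodonError(
            f"{snp.gene_id}:{snp.position}: codon {codon_index} "
            f"({ref_codon}) contains 'N'"
        )
    alt_codon = ref_codon[:offset - 1] + snp.alt_base + ref_codon[offset:]
    ref_aa = CODON_TO_AA[ref_codon]
    alt_aa = CODON_TO_AA[alt_codon]
    if ref_aa == alt_aa:
        effect = SILENT
    elif alt_aa == "*":
        effect = NONSENSE
    elif ref_aa == "*":
        effect = STOP_LOSS
    else:
        effect = MISSENSE
    return CodonEffect(
        gene_id=snp.gene_id,
        snp_position=snp.position,
        codon_index=codon_index,
        codon_offset=offset,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect_class=effect,
    )


def classify_all(
    orfs: Mapping[str, OrfSequence],
    snps: Sequence[SnpRecord],
    strict: bool = False,
) -> tuple[list[CodonEffect], list[tuple[SnpRecord, Exception]]]:
    """Classify a batch of SNPs, preserving input order.

    In the default lenient mode, per-record failures (ref-base mismatch,
    indeterminate codon, ...) are collected and returned alongside the
    successful effects instead of aborting the batch. An unknown gene id is
    always an error in strict mode; in lenient mode it is collected too.
    Returns ``(effects, failures)``.
    """
    effects: list[CodonEffect] = []
    failures: list[tuple[SnpRecord, Exception]] = []
    for snp in snps:
        try:
            orf = orfs.get(snp.gene_id)
            if orf is None:
                raise LookupError_(
                    f"SNP references unknown gene {snp.gene_id!r}"
                )
            effects.append(classify_snp_effect(orf, snp))
        except Exception as exc:
            if strict:
                raise
            failures.append((snp, exc))
    return effects, failures


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def map_genomic_to_orf(
    genomic_pos: int,
    orf_start: int,
    orf_end: int,
    strand: str,
    ref_base: str,
    alt_base: str,
) -> tuple[int, str, str]:
    """Map a chromosome coordinate into an intron-free ORF's coding frame.

    On '+' the position shifts by the ORF start; on '-' it is counted from the
    ORF end and both bases are complemented onto the coding strand.
    """
    if not orf_start <= genomic_pos <= orf_end:
        raise RangeError(
            f"genomic position {genomic_pos} outside ORF span "
            f"[{orf_start}, {orf_end}]"
        )
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if strand == "+":
        return genomic_pos - orf_start + 1, ref_base, alt_base
    if strand == "-":
        return (
            orf_end - genomic_pos + 1,
            _COMPLEMENT[ref_base],
            _COMPLEMENT[alt_base],
        )
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


# ---------------------------------------------------------------------------
# Effect table I/O

EFFECT_COLUMNS = (
    "gene_id", "position", "ref", "alt", "codon_index", "codon_offset",
    "ref_codon", "alt_codon", "ref_aa", "alt_aa", "effect_class",
)


def write_effect_table(
    effects: Sequence[CodonEffect], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EFFECT_COLUMNS) + "\n")
        for eff in effects:
            i = eff.codon_offset - 1
            fh.write(
                f"{eff.gene_id}\t{eff.snp_position}\t{eff.ref_codon[i]}\t"
                f"{eff.alt_codon[i]}\t{eff.codon_index}\t{eff.codon_offset}\t"
                f"{eff.ref_codon}\t{eff.alt_codon}\t{eff.ref_aa}\t"
                f"{eff.alt_aa}\t{eff.effect_class}\n"
            )
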