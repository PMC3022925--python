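"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the genetic code is
spelled out from the classic compact 64-character encoding, and the
hypergeometric tail is computed by exhaustive enumeration of draws.
"""

from itertools import combinations, product

# standard nuclear genetic code from the compact TCAG-ordered string
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE = {
    b1 + b2 + b3: _AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}


def translate_codon(codon: str) -> str:
    return GENETIC_CODE[codon]


def all_single_base_substitutions():
    """All 576 (ref_codon, offset, alt_base) single-base substitution cases."""
    for codon in GENETIC_CODE:
        for offset in range(3):
            for alt in "ACGT":
                if alt != codon[offset]:
                    yield codon, offset, alt


def classify_pair(ref_codon: str, alt_codon: str) -> str:
    """Brute-force effect class from two translated codons."""
    ref_aa, alt_aa = GENETIC_CODE[ref_codon], GENETIC_CODE[alt_codon]
    if ref_aa == alt_aa:
        return "silent"
    if alt_aa == "*":
        return "nonsynonymous_nonsense"
    if ref_aa == "*":
        return "stop_loss"
    return "nonsynonymous_missense"


def hypergeom_tail_by_enumeration(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by enumerating every size-n draw from an N-element universe.

    Only feasible for small N; the marked elements are the first K.
    """
    marked = set(range(K))
    total = 0
    hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def locate_column_by_scan(reference_row: str, protein_position: int) -> int:
    """1-based aligned column of the n-th non-gap reference character."""
    count = 0
    for col, ch in enumerate(reference_row, start=1):
        if ch != "-":
            count += 1
            if count == protein_position:
                return col
    raise ValueError("position beyond ungapped length")


def orf_to_genomic(orf_position: int, orf_start: int, orf_end: int,
                   strand: str) -> int:
    """Independent inverse of the genomic->ORF coordinate mapping."""
    if strand == "+":
        return orf_start + orf_position - 1
    return orf_end - orf_position + 1
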