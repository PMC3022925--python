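"""Per-SNP conservation statistics over homologue alignment columns.

For a nonsynonymous SNP at a given residue of the reference protein, the
homologue residues at the corresponding alignment column are profiled:

* reference match frequency — fraction of homologue residues equal to the
  reference-strain (S288c) residue;
* variant match frequency — fraction equal to the variant-strain (CEN.PK)
  residue;
* dominant residue frequency — the most common homologue residue's fraction;
* Conservation Distance — reference match frequency minus variant match
  frequency, bound in [-1, +1]: +1 when the homologues uniformly carry the
  reference residue, -1 when they uniformly carry the variant.

The reference row is excluded from all denominators, and gapped homologue
positions are not counted.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Sequence

from .errors import EmptyColumnError, EmptyInputError, RangeError, ValidationError
from .io_formats import HomologAlignmentSet


@dataclass(frozen=True)
class ConservationStats:
    gene_id: str
    protein_position: int          # 1-based residue index in the reference
    s288c_match_freq: float        # homologues matching the reference residue
    cenpk_match_freq: float        # homologues matching the variant residue
    dominant_aa: str
    dominant_aa_freq: float
    conservation_distance: float   # s288c_match_freq - cenpk_match_freq
    n_homologs_counted: int

    def __post_init__(self) -> None:
        if not math.isclose(
            self.conservation_distance,
            self.s288c_match_freq - self.cenpk_match_freq,
            abs_tol=1e-12,
        ):
            raise ValidationError("conservation_distance inconsistent")
        if self.dominant_aa_freq + 1e-12 < max(
            self.s288c_match_freq, self.cenpk_match_freq
        ):
            raise ValidationError("dominant frequency below a match frequency")


def locate_alignment_column(
    alignment: HomologAlignmentSet, protein_position: int
) -> int:
    """Aligned column (1-based) holding the reference row's n-th residue."""
    if protein_position < 1:
        raise RangeError(f"protein position {protein_position} < 1")
    seen = 0
    for col, ch in enumerate(alignment.reference_row, start=1):
        if ch != "-":
            seen += 1
            if seen == protein_position:
                return col
    raise RangeError(
        f"alignment {alignment.gene_id!r}: reference row has only {seen} "
        f"residues, position {protein_position} requested"
    )


def conservation_stats(
    alignment: HomologAlignmentSet,
    protein_position: int,
    ref_aa: str,
    variant_aa: str,
    top_k: int | None = None,
) -> ConservationStats:
    """Compute match frequencies and Conservation Distance for one SNP site.

    ``ref_aa`` must agree with the reference row at ``protein_position``
    (consistency check against mis-mapped coordinates). ``top_k`` truncates
    the homologue set to the first k rows in file order (the usual setting is
    the top 10 hits of the homologue search).
    """
    ref_aa, variant_aa = ref_aa.upper(), variant_aa.upper()
    col = locate_alignment_column(alignment, protein_position)
    found = alignment.reference_row[col - 1]
    if found != ref_aa:
        raise ValidationError(
            f"alignment {alignment.gene_id!r}: reference residue at protein "
            f"position {protein_position} is {found!r}, expected {ref_aa!r}"
        )
    homologs = alignment.homolog_rows()
    if top_k is not None:
        homologs = homologs[:top_k]
    residues = [row[col - 1] for _, row in homologs]
    residues = [r for r in residues if r != "-"]
    if not residues:
        raise EmptyColumnError(
            f"alignment {alignment.gene_id!r}: no ungapped homologue residues "
            f"at column {col}"
        )
    n = len(residues)
    counts: dict[str, int] = {}
    for r in residues:
        counts[r] = counts.get(r, 0) + 1
    s288c = counts.get(ref_aa, 0) / n
    cenpk = counts.get(variant_aa, 0) / n
    # ties broken alphabetically; the reported frequency is tie-independent
    dominant = min(counts, key=lambda r: (-counts[r], r))
    return ConservationStats(
        gene_id=alignment.gene_id,
        protein_position=protein_position,
        s288c_match_freq=s288c,
        cenpk_match_freq=cenpk,
        dominant_aa=dominant,
        dominant_aa_freq=counts[dominant] / n,
        conservation_distance=s288c - cenpk,
        n_homologs_counted=n,
    )


def mean_conservation_distance(
    stats_list: Sequence[ConservationStats],
) -> tuple[float, float, int]:
    """Mean and sample standard deviation (n-1) of Conservation Distance.

    A single observation reports sd 0.0 (undefined with n=1).
    """
    if not stats_list:
        raise EmptyInputError("no conservation statistics supplied")
    values = [s.conservation_distance for s in stats_list]
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0, 1
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var), n


CONSERVATION_COLUMNS = (
    "gene_id", "protein_position", "ref_aa", "variant_aa",
    "s288c_match_freq", "cenpk_match_freq", "dominant_aa",
    "dominant_aa_freq", "conservation_distance", "n_homologs",
)


def write_conservation_table(
    rows: Sequence[tuple[str, str, ConservationStats]],
    path: str | os.PathLike,
) -> None:
    """Write (ref_aa, variant_aa, stats) rows as the conservation table."""
    with open(path, "w") as fh:
        fh.write("\t".join(CONSERVATION_COLUMNS) + "\n")
        for ref_aa, variant_aa, s in rows:
            fh.write(
                f"{s.gene_id}\t{s.protein_position}\t{ref_aa}\t{variant_aa}\t"
                f"{s.s288c_match_freq:.6g}\t{s.cenpk_match_freq:.6g}\t"
                f"{s.dominant_aa}\t{s.dominant_aa_freq:.6g}\t"
                f"{s.conservation_distance:.6g}\t{s.n_homologs_counted}\n"
            )
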