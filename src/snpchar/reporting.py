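"""Summary counts and per-gene rollups of classified SNP effects.

"Nonsynonymous" in all summaries is the two-way rollup: missense + nonsense
+ stop-loss. Percentages are displayed to one decimal but stored at full
precision.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .codon_effects import CodonEffect, is_nonsynonymous
from .errors import MembershipError, ValidationError


@dataclass(frozen=True)
class SummaryCounts:
    n_genes_considered: int
    n_snps_total: int
    n_snps_nonsyn: int
    n_genes_with_snp: int
    n_genes_with_nonsyn: int

    def __post_init__(self) -> None:
        if self.n_snps_nonsyn > self.n_snps_total:
            raise ValidationError("nonsynonymous count exceeds SNP total")
        if not (
            self.n_genes_with_nonsyn
            <= self.n_genes_with_snp
            <= self.n_genes_considered
        ):
            raise ValidationError("gene counts are not nested")

    @property
    def pct_nonsyn(self) -> float:
        """Full-precision percentage of SNPs that are nonsynonymous."""
        if self.n_snps_total == 0:
            return 0.0
        return 100.0 * self.n_snps_nonsyn / self.n_snps_total

    @property
    def pct_nonsyn_display(self) -> float:
        """Table-style display value, rounded to one decimal."""
        return round(self.pct_nonsyn, 1)

    @classmethod
    def from_totals(
        cls,
        n_snps_total: int,
        n_snps_nonsyn: int,
        n_genes_considered: int = 0,
        n_genes_with_snp: int = 0,
        n_genes_with_nonsyn: int = 0,
    ) -> "SummaryCounts":
        """Build a summary directly from published-style count pairs."""
        return cls(
            n_genes_considered=n_genes_considered,
            n_snps_total=n_snps_total,
            n_snps_nonsyn=n_snps_nonsyn,
            n_genes_with_snp=n_genes_with_snp,
            n_genes_with_nonsyn=n_genes_with_nonsyn,
        )

    def to_dict(self) -> dict:
        return {
            "n_genes_considered": self.n_genes_considered,
            "n_snps_total": self.n_snps_total,
            "n_snps_nonsyn": self.n_snps_nonsyn,
            "pct_nonsyn": self.pct_nonsyn_display,
            "n_genes_with_snp": self.n_genes_with_snp,
            "n_genes_with_nonsyn": self.n_genes_with_nonsyn,
        }


def summarize(
    effects: Sequence[CodonEffect], considered_genes: Iterable[str]
) -> SummaryCounts:
    """Aggregate classified effects over a declared set of considered genes."""
    considered = frozenset(considered_genes)
    stray = {e.gene_id for e in effects} - considered
    if stray:
        raise MembershipError(
            f"effects reference genes outside the considered set: "
            f"{sorted(stray)!r}"
        )
    nonsyn = [e for e in effects if is_nonsynonymous(e.effect_class)]
    return SummaryCounts(
        n_genes_considered=len(considered),
        n_snps_total=len(effects),
        n_snps_nonsyn=len(nonsyn),
        n_genes_with_snp=len({e.gene_id for e in effects}),
        n_genes_with_nonsyn=len({e.gene_id for e in nonsyn}),
    )


def per_gene_rollup(effects: Sequence[CodonEffect]) -> pd.DataFrame:
    """Per-gene SNP counts: one row per gene with >=1 SNP.

    Columns ``n_snps`` and ``n_nonsyn``; column sums equal the global totals.
    """
    rows: dict[str, list[int]] = {}
    for e in effects:
        cell = rows.setdefault(e.gene_id, [0, 0])
        cell[0] += 1
        if is_nonsynonymous(e.effect_class):
            cell[1] += 1
    df = pd.DataFrame(
        [(g, c[0], c[1]) for g, c in rows.items()],
        columns=["gene_id", "n_snps", "n_nonsyn"],
    )
    return df.set_index("gene_id")


def write_summary_json(summary: SummaryCounts, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
        fh.write("\n")


def write_summary_tsv(summary: SummaryCounts, path: str | os.PathLike) -> None:
    d = summary.to_dict()
    with open(path, "w") as fh:
        fh.write("\t".join(d.keys()) + "\n")
        fh.write("\t".join(str(v) for v in d.values()) + "\n")
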