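"""MAQ SNPfilter-style threshold cascade for candidate SNPs.

A candidate passes only if read depth d > 5, local max depth D < 255, region
uniqueness w < 1.5, consensus quality Q > 50, best neighbouring read quality
n > 40, and the called alternate base is unambiguous. All comparisons are
strict by default (boundary values fail); an inclusive mode is available for
sensitivity analysis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

from .errors import ParseError, ValidationError
from .io_formats import SnpRecord

#: rule codes in reporting order
RULE_CODES = ("d", "D", "w", "Q", "n", "ambiguous")


@dataclass(frozen=True)
class CandidateSnp:
    """A called SNP candidate with MAQ-style quality fields.

    d: read depth at the site; D: maximum depth in the surrounding window;
    w: region uniqueness score; Q: phred-scaled consensus quality;
    n: phred-scaled quality of the best neighbouring read;
    ambiguous: True when the called alternate is not a single unambiguous base.
    """

    core: SnpRecord
    d: int
    D: int
    w: float
    Q: float
    n: float
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.d < 0 or self.D < self.d:
            raise ValidationError(
                f"candidate {self.core.gene_id}:{self.core.position}: "
                f"need 0 <= d <= D, got d={self.d}, D={self.D}"
            )
        if self.Q < 0 or self.n < 0 or self.w < 0:
            raise ValidationError(
                f"candidate {self.core.gene_id}:{self.core.position}: "
                "quality fields must be non-negative"
            )


@dataclass(frozen=True)
class FilterThresholds:
    """Threshold cascade; defaults are the published SNPfilter settings."""

    d_min: int = 5
    D_max: int = 255
    w_max: float = 1.5
    Q_min: float = 50.0
    n_min: float = 40.0
    inclusive: bool = False  # boundary values pass instead of fail

    def __post_init__(self) -> None:
        if self.d_min >= self.D_max:
            raise ValidationError(
                f"d_min ({self.d_min}) must be below D_max ({self.D_max})"
            )

    def violations(self, cand: CandidateSnp) -> tuple[str, ...]:
        """Codes of every rule the candidate violates (empty = pass)."""
        if self.inclusive:
            checks = (
                cand.d >= self.d_min,
                cand.D <= self.D_max,
                cand.w <= self.w_max,
                cand.Q >= self.Q_min,
                cand.n >= self.n_min,
            )
        else:
            checks = (
                cand.d > self.d_min,
                cand.D < self.D_max,
                cand.w < self.w_max,
                cand.Q > self.Q_min,
                cand.n > self.n_min,
            )
        codes = [c for c, ok in zip(RULE_CODES, checks) if not ok]
        if cand.ambiguous:
            codes.append("ambiguous")
        return tuple(codes)


def filter_candidates(
    candidates: Sequence[CandidateSnp],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[SnpRecord], list[tuple[CandidateSnp, tuple[str, ...]]]]:
    """Partition candidates into passing SNP records and rejects.

    Every reject carries the codes of all violated rules, not just the first.
    Input order is preserved on both sides of the partition.
    """
    thresholds = thresholds or FilterThresholds()
    passed: list[SnpRecord] = []
    rejected: list[tuple[CandidateSnp, tuple[str, ...]]] = []
    for cand in candidates:
        reasons = thresholds.violations(cand)
        if reasons:
            rejected.append((cand, reasons))
        else:
            passed.append(cand.core)
    return passed, rejected


def filter_ambiguous(candidates: Sequence[CandidateSnp]) -> list[CandidateSnp]:
    """Drop candidates whose called alternate base is ambiguous."""
    return [c for c in candidates if not c.ambiguous]


# ---------------------------------------------------------------------------
# Candidate table I/O

CANDIDATE_COLUMNS = (
    "gene_id", "position", "ref", "alt", "d", "D", "w", "Q", "n", "ambiguous",
)


def read_candidate_table(path: str | os.PathLike) -> list[CandidateSnp]:
    with open(path) as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != CANDIDATE_COLUMNS:
            raise ParseError(
                f"{path}: line 1: expected header "
                f"{' '.join(CANDIDATE_COLUMNS)!r}"
            )
        out: list[CandidateSnp] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != len(CANDIDATE_COLUMNS):
                raise ParseError(
                    f"{path}: line {lineno}: expected "
                    f"{len(CANDIDATE_COLUMNS)} columns, got {len(f)}"
                )
            try:
                core = SnpRecord(f[0], int(f[1]), f[2], f[3])
                out.append(CandidateSnp(
                    core, d=int(f[4]), D=int(f[5]), w=float(f[6]),
                    Q=float(f[7]), n=float(f[8]),
                    ambiguous=f[9].lower() in ("1", "true", "yes"),
                ))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        return out


def write_candidate_table(
    candidates: Sequence[CandidateSnp], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for c in candidates:
            s = c.core
            fh.write(
                f"{s.gene_id}\t{s.position}\t{s.ref_base}\t{s.alt_base}\t"
                f"{c.d}\t{c.D}\t{c.w:g}\t{c.Q:g}\t{c.n:g}\t"
                f"{'true' if c.ambiguous else 'false'}\n"
            )
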