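"""Hypergeometric term over-representation with multiple-testing correction.

Given a study gene set (e.g. genes carrying nonsynonymous SNPs), a background
universe and gene->term annotations, each term's upper-tail hypergeometric
probability P(X >= k) is computed (k study genes with the term, out of n
study genes, K term genes in a universe of N), then corrected across terms by
Benjamini-Hochberg (default) or Bonferroni.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import MembershipError, ParseError, ValidationError


@dataclass(frozen=True)
class TermAnnotation:
    term_id: str
    term_name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"term {self.term_id!r}: empty gene set")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int          # study genes carrying the term
    n: int          # study set size
    K: int          # universe genes carrying the term
    N: int          # universe size
    p_value: float
    p_adj: float
    enriched: bool


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), stable in log space."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValidationError(
            f"invalid hypergeometric bounds: k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    # sf is exclusive of k, hence k-1
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    study: Iterable[str],
    annotations: Sequence[TermAnnotation],
    universe: Iterable[str] | None = None,
    alpha: float = 0.01,
    correction: str = "bh",
) -> list[EnrichmentResult]:
    """Test every term for over-representation in the study set.

    The universe defaults to all annotated genes plus the study genes.
    Terms with no gene in the universe are skipped. Results are sorted by
    ascending raw p-value (term id breaking ties) and flagged enriched when
    the adjusted p-value falls below ``alpha``.
    """
    study_set = frozenset(study)
    if universe is None:
        uni: set[str] = set(study_set)
        for ann in annotations:
            uni |= ann.genes
        universe_set = frozenset(uni)
    else:
        universe_set = frozenset(universe)
        missing = study_set - universe_set
        if missing:
            raise MembershipError(
                f"study genes absent from universe: {sorted(missing)!r}"
            )
    N = len(universe_set)
    n = len(study_set)
    tested: list[tuple[TermAnnotation, int, int, float]] = []
    for ann in annotations:
        term_genes = ann.genes & universe_set
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & study_set)
        tested.append((ann, k, K, hypergeom_upper_tail(k, n, K, N)))
    if not tested:
        return []
    pvals = [t[3] for t in tested]
    method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(correction)
    if method is None:
        raise ValueError(f"unknown correction {correction!r}")
    _, p_adj, _, _ = multipletests(pvals, method=method)
    results = [
        EnrichmentResult(
            term_id=ann.term_id,
            term_name=ann.term_name,
            k=k, n=n, K=K, N=N,
            p_value=p,
            p_adj=float(min(1.0, max(p, adj))),
            enriched=bool(adj < alpha),
        )
        for (ann, k, K, p), adj in zip(tested, p_adj)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


# ---------------------------------------------------------------------------
# Annotation table I/O (GAF-lite: gene_id <TAB> term_id <TAB> term_name)


def read_annotation_table(path: str | os.PathLike) -> list[TermAnnotation]:
    """Read gene->term annotations, preserving first-seen term order."""
    genes_by_term: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected "
                    "gene_id<TAB>term_id[<TAB>term_name]"
                )
            gene, term = fields[0], fields[1]
            name = fields[2] if len(fields) > 2 else term
            genes_by_term.setdefault(term, set()).add(gene)
            names.setdefault(term, name)
    return [
        TermAnnotation(term, names[term], frozenset(genes))
        for term, genes in genes_by_term.items()
    ]


def write_annotation_table(
    annotations: Sequence[TermAnnotation], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            for gene in sorted(ann.genes):
                fh.write(f"{gene}\t{ann.term_id}\t{ann.term_name}\n")


ENRICHMENT_COLUMNS = (
    "term_id", "term_name", "k", "n", "K", "N", "p_value", "p_adj", "enriched",
)


def write_enrichment_table(
    results: Sequence[EnrichmentResult], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ENRICHMENT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                f"{r.p_value:.6g}\t{r.p_adj:.6g}\t"
                f"{'true' if r.enriched else 'false'}\n"
            )
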