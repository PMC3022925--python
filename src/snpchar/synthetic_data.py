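"""Seeded generator for offline test data emulating the study's inputs.

Produces ORFs with standard genetic-code structure (ATG start, single
terminal stop, no internal stop), spiked SNP candidates with MAQ-like
quality fields and generator-recorded ground-truth effect labels, homologue
protein alignments with controlled per-column conservation, and a small
gene->term annotation table.

Every artifact draws from its own pseudo-random stream spawned from the
master seed, so regenerating one artifact never perturbs the others, and an
identical configuration yields byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from Bio.Seq import Seq

from .errors import CapacityError, ConfigError
from .io_formats import (
    HomologAlignmentSet,
    OrfSequence,
    SnpRecord,
    write_alignment,
    write_orf_fasta,
)
from .snp_filtering import (
    CandidateSnp,
    FilterThresholds,
    write_candidate_table,
)
from .enrichment import TermAnnotation, write_annotation_table

BASES = ("A", "C", "G", "T")
STOP_CODONS = ("TAA", "TAG", "TGA")
RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")

SILENT = "silent"
MISSENSE = "nonsynonymous_missense"
NONSENSE = "nonsynonymous_nonsense"
STOP_LOSS = "stop_loss"


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults emulate the published analysis scale where one is printed: ten
    homologues per gene (the "top 10" homologue query) and a nonsynonymous
    target fraction of 0.233 (the metabolic-gene nonsynonymous percentage).
    The remaining knobs (gene count and length, SNP rate, conservation,
    pass fraction) are desk-scale choices documented in the methods note.
    """

    seed: int = 0
    n_genes: int = 20
    codon_length_range: tuple[int, int] = (60, 180)  # incl. start and stop
    snps_per_gene: float = 5.0
    target_nonsyn_fraction: float = 0.233
    n_homologs: int = 10
    column_conservation: float = 0.7
    gap_fraction: float = 0.05
    quality_pass_fraction: float = 0.8
    annotation_terms: int = 5
    genes_per_term_range: tuple[int, int] = (3, 8)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        for name, rng_ in (
            ("codon_length_range", self.codon_length_range),
            ("genes_per_term_range", self.genes_per_term_range),
        ):
            lo, hi = rng_
            if lo > hi:
                raise ConfigError(f"{name}: min {lo} > max {hi}")
        if self.codon_length_range[0] < 2:
            raise ConfigError("ORFs need at least 2 codons (start + stop)")
        for name, frac in (
            ("target_nonsyn_fraction", self.target_nonsyn_fraction),
            ("column_conservation", self.column_conservation),
            ("gap_fraction", self.gap_fraction),
            ("quality_pass_fraction", self.quality_pass_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {frac}")


def sim_config_from_yaml(path: str | os.PathLike) -> SimConfig:
    """Load a flat key-value YAML file mirroring the SimConfig fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("codon_length_range", "genes_per_term_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimConfig(**raw)


@dataclass(frozen=True)
class SnpTruth:
    """Ground truth recorded at spike time for one synthetic SNP."""

    record: SnpRecord
    effect_class: str
    passes_filter: bool


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    names = ("orfs", "snps", "quality", "alignments", "annotations")
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# ORFs


def generate_orfs(
    config: SimConfig, rng: np.random.Generator | None = None
) -> dict[str, OrfSequence]:
    """Generate ORFs: ATG, uniform-composition sense codons, one stop."""
    rng = rng if rng is not None else _streams(config)["orfs"]
    lo, hi = config.codon_length_range
    orfs: dict[str, OrfSequence] = {}
    for i in range(config.n_genes):
        gene_id = f"G{i + 1:04d}"
        n_codons = int(rng.integers(lo, hi + 1))
        codons = ["ATG"]
        for _ in range(n_codons - 2):
            # uniform base composition conditional on not being a stop codon
            while True:
                codon = "".join(BASES[b] for b in rng.integers(0, 4, size=3))
                if codon not in STOP_CODONS:
                    break
            codons.append(codon)
        codons.append(STOP_CODONS[rng.integers(0, 3)])
        orfs[gene_id] = OrfSequence(
            gene_id, "".join(codons), "synthetic ORF"
        )
    return orfs


# ---------------------------------------------------------------------------
# SNP spiking


def _classify_substitution(
    seq: str, position: int, alt_base: str
) -> str:
    ci = (position - 1) // 3
    off = (position - 1) % 3
    ref_codon = seq[3 * ci:3 * ci + 3]
    alt_codon = ref_codon[:off] + alt_base + ref_codon[off + 1:]
    ref_aa = _translate_codon(ref_codon)
    alt_aa = _translate_codon(alt_codon)
    if ref_aa == alt_aa:
        return SILENT
    if alt_aa == "*":
        return NONSENSE
    if ref_aa == "*":
        return STOP_LOSS
    return MISSENSE


def _draw_substitution(
    orf: OrfSequence,
    want_nonsyn: bool,
    used: set[int],
    rng: np.random.Generator,
    max_tries: int = 20000,
) -> tuple[int, str, str, str]:
    """Rejection-sample (position, ref, alt, effect) of the wanted class."""
    seq = orf.sequence
    for _ in range(max_tries):
        pos = int(rng.integers(1, len(seq) + 1))
        if pos in used:
            continue
        ref = seq[pos - 1]
        alt = BASES[rng.integers(0, 4)]
        if alt == ref:
            continue
        effect = _classify_substitution(seq, pos, alt)
        if (effect != SILENT) == want_nonsyn:
            used.add(pos)
            return pos, ref, alt, effect
    raise CapacityError(
        f"ORF {orf.gene_id!r}: could not place a "
        f"{'nonsynonymous' if want_nonsyn else 'silent'} SNP "
        f"({len(used)}/{len(seq)} positions used)"
    )


def _draw_quality(
    should_pass: bool,
    rng: np.random.Generator,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[int, int, float, float, float, bool]:
    """Quality fields constructed to pass or violate the default cascade."""
    d = int(rng.integers(thresholds.d_min + 1, 101))
    D = int(rng.integers(d, thresholds.D_max))
    w = float(rng.uniform(0.0, thresholds.w_max * 0.99))
    Q = float(rng.uniform(thresholds.Q_min + 1.0, 99.0))
    n = float(rng.uniform(thresholds.n_min + 1.0, 99.0))
    ambiguous = False
    if not should_pass:
        rule = int(rng.integers(0, 6))
        if rule == 0:
            d = int(rng.integers(0, thresholds.d_min + 1))
            D = max(D, d)
        elif rule == 1:
            D = int(rng.integers(thresholds.D_max, thresholds.D_max + 200))
        elif rule == 2:
            w = float(rng.uniform(thresholds.w_max, thresholds.w_max * 3))
        elif rule == 3:
            Q = float(rng.uniform(0.0, thresholds.Q_min))
        elif rule == 4:
            n = float(rng.uniform(0.0, thresholds.n_min))
        else:
            ambiguous = True
    return d, D, round(w, 3), round(Q, 1), round(n, 1), ambiguous


def spike_snps(
    orfs: Mapping[str, OrfSequence],
    config: SimConfig,
    n_total: int | None = None,
    rng: np.random.Generator | None = None,
    quality_rng: np.random.Generator | None = None,
) -> tuple[list[CandidateSnp], list[SnpTruth]]:
    """Spike SNPs into ORFs with a controlled nonsynonymous composition.

    Exactly ``round(target_nonsyn_fraction * total)`` SNPs are nonsynonymous
    (the closest achievable composition); substitutions are rejection-sampled
    by their true codon consequence. ``n_total`` fixes the total SNP count;
    otherwise each gene draws a Poisson(snps_per_gene) count. Quality fields
    are constructed so that, per candidate, a Bernoulli(quality_pass_fraction)
    draw decides whether the default filter cascade passes it; the returned
    truth table records every label.
    """
    if rng is None or quality_rng is None:
        streams = _streams(config)
        rng = rng if rng is not None else streams["snps"]
        quality_rng = (
            quality_rng if quality_rng is not None else streams["quality"]
        )
    gene_ids = list(orfs)
    counts: dict[str, int] = {g: 0 for g in gene_ids}
    if n_total is None:
        for g in gene_ids:
            counts[g] = min(
                int(rng.poisson(config.snps_per_gene)), len(orfs[g])
            )
    else:
        capacity = {g: len(orfs[g]) for g in gene_ids}
        if n_total > sum(capacity.values()):
            raise CapacityError(
                f"requested {n_total} SNPs exceed total capacity "
                f"{sum(capacity.values())}"
            )
        placed = 0
        while placed < n_total:
            g = gene_ids[rng.integers(0, len(gene_ids))]
            if counts[g] < capacity[g]:
                counts[g] += 1
                placed += 1
    total = sum(counts.values())
    n_nonsyn = round(config.target_nonsyn_fraction * total)
    labels = np.zeros(total, dtype=bool)
    labels[:n_nonsyn] = True
    rng.shuffle(labels)

    candidates: list[CandidateSnp] = []
    truth: list[SnpTruth] = []
    idx = 0
    for g in gene_ids:
        used: set[int] = set()
        for _ in range(counts[g]):
            want_nonsyn = bool(labels[idx])
            idx += 1
            pos, ref, alt, effect = _draw_substitution(
                orfs[g], want_nonsyn, used, rng
            )
            record = SnpRecord(g, pos, ref, alt, strain_label="CEN.PK113-7D")
            should_pass = bool(quality_rng.random() < config.quality_pass_fraction)
            d, D, w, Q, n, amb = _draw_quality(should_pass, quality_rng)
            candidates.append(
                CandidateSnp(record, d=d, D=D, w=w, Q=Q, n=n, ambiguous=amb)
            )
            truth.append(SnpTruth(record, effect, should_pass))
    return candidates, truth


# ---------------------------------------------------------------------------
# Homologue alignments


def generate_homolog_alignment(
    orf: OrfSequence,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    overrides: Mapping[int, tuple[str, str | None]] | None = None,
) -> HomologAlignmentSet:
    """Simulate a homologue alignment around the translated ORF.

    The reference row is the ORF's protein (terminal stop stripped, no gaps).
    Each homologue copies the reference residue with probability
    ``column_conservation``, is gapped with probability ``gap_fraction``, and
    otherwise carries a uniformly random different residue.

    ``overrides`` maps a protein position to ``("all_ref", None)`` or
    ``("all_variant", variant_residue)``, forcing every homologue at that
    column to the reference or to the given variant residue — the extreme
    compositions whose Conservation Distance is +1 and -1 respectively.
    """
    rng = rng if rng is not None else _streams(config)["alignments"]
    overrides = overrides or {}
    protein = str(Seq(orf.sequence).translate()).rstrip("*")
    n_cols = len(protein)
    rows = [protein]
    row_ids = ["S288c"]
    for h in range(config.n_homologs):
        chars = []
        for col in range(1, n_cols + 1):
            ref_res = protein[col - 1]
            if col in overrides:
                mode, variant = overrides[col]
                if mode == "all_ref":
                    chars.append(ref_res)
                elif mode == "all_variant":
                    if variant is None:
                        raise ConfigError(
                            "all_variant override needs a variant residue"
                        )
                    chars.append(variant)
                else:
                    raise ConfigError(f"unknown override mode {mode!r}")
                continue
            u = rng.random()
            if u < config.gap_fraction:
                chars.append("-")
            elif u < config.gap_fraction + (1 - config.gap_fraction) * config.column_conservation:
                chars.append(ref_res)
            else:
                others = [r for r in RESIDUES if r != ref_res]
                chars.append(others[rng.integers(0, len(others))])
        rows.append("".join(chars))
        row_ids.append(f"hom{h + 1:02d}")
    return HomologAlignmentSet(
        orf.gene_id, "S288c", tuple(row_ids), tuple(rows)
    )


# ---------------------------------------------------------------------------
# Annotations


def generate_annotations(
    gene_ids: Sequence[str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[TermAnnotation]:
    rng = rng if rng is not None else _streams(config)["annotations"]
    lo, hi = config.genes_per_term_range
    terms: list[TermAnnotation] = []
    for t in range(config.annotation_terms):
        size = min(int(rng.integers(lo, hi + 1)), len(gene_ids))
        genes = rng.choice(len(gene_ids), size=size, replace=False)
        terms.append(
            TermAnnotation(
                term_id=f"T{t + 1:03d}",
                term_name=f"synthetic pathway {t + 1}",
                genes=frozenset(gene_ids[int(i)] for i in genes),
            )
        )
    return terms


# ---------------------------------------------------------------------------
# Whole datasets


@dataclass(frozen=True)
class Dataset:
    config: SimConfig
    orfs: dict[str, OrfSequence]
    candidates: list[CandidateSnp]
    truth: list[SnpTruth]
    alignments: dict[str, HomologAlignmentSet]
    annotations: list[TermAnnotation]


def generate_dataset(config: SimConfig, n_total_snps: int | None = None) -> Dataset:
    """Generate all artifacts from independent per-artifact streams."""
    streams = _streams(config)
    orfs = generate_orfs(config, streams["orfs"])
    candidates, truth = spike_snps(
        orfs, config, n_total=n_total_snps,
        rng=streams["snps"], quality_rng=streams["quality"],
    )
    alignments = {
        g: generate_homolog_alignment(orf, config, streams["alignments"])
        for g, orf in orfs.items()
    }
    annotations = generate_annotations(list(orfs), config, streams["annotations"])
    return Dataset(config, orfs, candidates, truth, alignments, annotations)


TRUTH_COLUMNS = ("gene_id", "position", "ref", "alt", "effect_class", "passes_filter")


def write_truth_table(truth: Sequence[SnpTruth], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            r = t.record
            fh.write(
                f"{r.gene_id}\t{r.position}\t{r.ref_base}\t{r.alt_base}\t"
                f"{t.effect_class}\t{'true' if t.passes_filter else 'false'}\n"
            )


def write_dataset(dataset: Dataset, outdir: str | os.PathLike) -> None:
    """Write orfs.fasta, candidates.tsv, truth.tsv, alignments/, annotations.tsv."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_orf_fasta(dataset.orfs, out / "orfs.fasta")
    write_candidate_table(dataset.candidates, out / "candidates.tsv")
    write_truth_table(dataset.truth, out / "truth.tsv")
    aln_dir = out / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for gene_id, aln in dataset.alignments.items():
        write_alignment(aln, aln_dir / f"{gene_id}.afa")
    write_annotation_table(dataset.annotations, out / "annotations.tsv")
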