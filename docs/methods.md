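# Methods

## Scope and data model

The package characterizes single-nucleotide substitutions between a
reference yeast strain (S288c) and a query strain (CEN.PK113-7D) at the
level of individual ORFs. All coordinates are 1-based and ORF-relative on
the coding strand; supplied sequences are assumed to be spliced coding
sequences read in frame 1 (ATG … stop). Genomic coordinates enter only
through `codon_effects.map_genomic_to_orf`, which handles contiguous
(intron-free) ORFs on either strand, complementing bases for '−' genes.

Inputs are plain text: ORF FASTA, tab-separated SNP/candidate tables (a
VCF 4.x subset is accepted, with CHROM read as the gene id and POS as the
ORF-relative position, INFO/FILTER ignored), aligned FASTA or Stockholm
homologue alignments ('.' gaps normalized to '-'), and a
`gene<TAB>term<TAB>name` annotation table.

## Quality filter cascade

Candidates carry the MAQ-style fields d (site read depth), D (maximum depth
in the surrounding window), w (region uniqueness), Q (consensus quality),
n (best neighbouring read quality), and an ambiguity flag. A candidate
passes iff

    d > 5  and  D < 255  and  w < 1.5  and  Q > 50  and  n > 40
    and the alternate base is a single unambiguous nucleotide.

All comparisons are strict — the operators are read literally, so boundary
values (d = 5, Q = 50) fail. `FilterThresholds(inclusive=True)` switches to
closed bounds for sensitivity analysis. Rejected candidates report *every*
violated rule, not only the first, and filtering partitions its input
(passed + rejected = input, order preserved). The upstream read mapping and
consensus calling that produce the quality fields are out of scope; w in
particular is treated as an opaque supplied number.

## Codon effect classification

Each SNP maps to codon ⌈p/3⌉ with offset ((p−1) mod 3)+1. Reference and
variant codons are translated under the standard nuclear genetic code
(table 1; a config hook exists for alternate tables, though the target
genes are nuclear). Classes:

* **silent** — residues equal (including stop→stop);
* **nonsynonymous_missense** — both residues coding, unequal;
* **nonsynonymous_nonsense** — variant codon is a stop, reference is not;
* **stop_loss** — reference codon is a stop, variant is not.

Reports that need the two-way silent/nonsynonymous split count missense,
nonsense and stop-loss together as nonsynonymous; the four-way class is kept
in per-record output. The classifier refuses ORFs whose length is not a
multiple of 3, SNPs whose stated reference base disagrees with the ORF, and
codons containing N. Batch classification collects such per-record failures
and continues (strict mode aborts), since one bad record should not abort a
multi-thousand-SNP run.

## Amino-acid property scheme

Residues map to *overlapping* property labels (polar, non-polar,
hydrophobic, hydrophilic, hydroxylic, charged, positive, negative,
aliphatic, aromatic, small, tiny, sulphur-containing, amidic). The packaged
scheme (`src/snpchar/data/aa_properties.tsv`, overridable via
`load_scheme`) is a Taylor-style Venn classification with one deliberate
adjustment: serine carries {polar, hydroxylic, small, tiny} and is *not*
hydrophobic, so that hydroxylic column profiles separate cleanly from
hydrophobic ones (some published schemes mark Thr/Tyr — and occasionally
Ser — hydrophobic; the choice matters only for profiles that mix those
labels and is documented here rather than hidden). Polar and non-polar are
enforced mutually exclusive; the stop symbol carries no labels.

Column profiles report, for each label, the fraction of *ungapped homologue*
residues at the column carrying that label; gapped positions leave the
denominator, and the reference row is excluded by default (profiles describe
the homologues). Because labels overlap, fractions need not sum to 1 —
a column of six serines and two alanines is simultaneously 75% polar,
25% non-polar, 25% hydrophobic and 75% hydroxylic.

## Conservation statistics

For a nonsynonymous SNP at reference-protein position i, the aligned column
holding the reference row's i-th non-gap residue is located, and over the
ungapped homologue residues there (reference row excluded, optional
`top_k` truncation in file order — default 10, matching a top-10 homologue
query):

* `s288c_match_freq` — fraction equal to the reference residue;
* `cenpk_match_freq` — fraction equal to the variant residue;
* `dominant_aa_freq` — the modal residue's fraction (ties broken
  alphabetically; the frequency itself is tie-independent);
* `conservation_distance` = s288c_match_freq − cenpk_match_freq.

The Conservation Distance is bound in [−1, +1]: +1 when homologues
uniformly support the reference residue, −1 when they uniformly support the
variant, 0 under symmetric support (and exactly 0 for a protein-silent
pair). It is antisymmetric under swapping the two residues. The difference
of match frequencies is the simplest statistic with these anchor
properties; it is adopted here as the package's definition. A consistency
check requires the supplied reference residue to equal the reference row at
the position, catching mis-mapped coordinates. `mean_conservation_distance`
reports the arithmetic mean and the n−1 sample standard deviation (sd 0
flagged with n = 1).

Sites where the reference or variant residue is a stop have no alignment
column and are skipped by the `conserve` CLI step with a warning count.

## Enrichment

For a study set of n genes in a universe of N, a term annotating K universe
genes with k of them in the study set scores the upper-tail hypergeometric
probability P(X ≥ k) (scipy's survival function at k−1; k = 0 gives exactly
1). The universe defaults to all annotated genes plus the study genes;
with an explicit universe, annotations are intersected with it and terms
left with K = 0 are skipped, while study genes outside the universe are an
error. Correction across terms is Benjamini–Hochberg by default (Bonferroni
available); a term is flagged enriched when the adjusted p-value falls
below α (default 0.01). No ontology-graph propagation is performed — terms
are independent gene sets.

## Synthetic data generator

The generator stands in for the strains' raw sequencing data and emulates
the study conditions: ten homologues per gene (the top-10 homologue
analysis) and a target nonsynonymous fraction of 0.233, the nonsynonymous
share observed among metabolic-gene SNPs. Desk-scale defaults chosen once
for the remaining knobs: 20 genes of 60–180 codons (uniform), Poisson(5)
SNPs per gene (a fixed total can be pinned), column conservation 0.7
(homologues of a conserved metabolic enzyme mostly match the reference),
5% gap injection, 80% of candidates passing the default quality cascade,
and 5 annotation terms of 3–8 genes.

Mechanics worth knowing:

* Every artifact (ORFs, SNPs, qualities, alignments, annotations) draws
  from its own stream spawned from the master seed, so regenerating one
  never perturbs the others; identical configurations yield byte-identical
  files.
* ORFs are ATG + uniform-composition sense codons (stop codons rejection-
  sampled away) + one random stop. No codon-usage model is applied — the
  analysis stages are composition-agnostic.
* SNP spiking assigns exactly round(target × total) nonsynonymous labels,
  then rejection-samples (position, alternate base) pairs until the true
  codon consequence — determined by direct translation, a separate code
  path from the classifier — matches the assigned label. Positions are
  unique per gene; an ORF too small for its quota raises a capacity error.
* Quality fields are constructed so a Bernoulli(quality_pass_fraction) draw
  decides the filter outcome: passing candidates sample every field inside
  the admissible region, failing ones violate one uniformly chosen rule.
* Homologue rows copy the reference residue with probability
  `column_conservation` (conditional on not being gapped), else a uniform
  different residue. Per-column overrides force all-reference or
  all-variant compositions, producing the ±1 Conservation Distance
  extremes for fixtures.

What the generator does **not** emulate: read-level errors, linkage between
nearby SNPs, phylogenetic correlation among homologues, codon usage, or
realistic annotation structure (terms are random gene sets, so enrichment
on synthetic data is null by construction). Passing tests therefore
demonstrate correctness of the statistics and plumbing, not biological
realism of any particular dataset.

## Numerical and design choices

* Hypergeometric tails come from scipy's log-space implementation; the test
  suite cross-checks it against exhaustive draw enumeration for N ≤ 12.
* BH adjustment is statsmodels' `multipletests`; adjusted values are
  clamped to [p, 1].
* Percentages are displayed to one decimal but stored at full precision.
* Determinism: all randomness flows through numpy `default_rng` seeded from
  explicit integers; the test suite's hypothesis profile is derandomized.
* Problem sizes in the test suite (10,000 filter candidates, 1,000 spiked
  SNPs, 219 conservation columns, 1,000 null enrichment draws) keep the
  whole suite within a few seconds while leaving sampling-error bounds
  meaningful.

## Known limitations

* Multi-nucleotide variants, indels, frameshifts and splice effects are out
  of scope; one SNP, one codon.
* The Conservation Distance formula is the package's anchored
  interpretation (difference of match frequencies); alternative gap or
  weighting policies over homologue sets are not implemented.
* Enrichment treats terms as flat gene sets — no ontology ancestor
  propagation or conditional (elim-style) testing.
* The filter stage assumes quality fields are already computed by an
  upstream caller; it cannot detect miscalibrated inputs.
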