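# Demo simulation: 20 genes, ~5 SNPs per gene, 10 homologues per gene,
# 5 annotation terms. The shipped examples/demo/ fixture was produced from
# this configuration with the total SNP count pinned to 100:
#   python -c "from snpchar import *; from snpchar.synthetic_data import *; \
#     write_dataset(generate_dataset(sim_config_from_yaml('examples/sim_demo.yaml'), \
#     n_total_snps=100), 'examples/demo')"
# (plain `snpchar simulate --config examples/sim_demo.yaml --out DIR` draws
# per-gene Poisson counts instead of pinning the total)
seed: 7
n_genes: 20
codon_length_range: [60, 120]
snps_per_gene: 5.0
target_nonsyn_fraction: 0.233
n_homologs: 10
column_conservation: 0.7
gap_fraction: 0.05
quality_pass_fraction: 0.8
annotation_terms: 5
genes_per_term_range: [3, 8]
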