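import numpy as np
import pytest

from snpchar import (
    FilterThresholds,
    SimConfig,
    classify_all,
    conservation_stats,
    generate_dataset,
    generate_homolog_alignment,
    generate_orfs,
    spike_snps,
)
from snpchar.codon_effects import SILENT
from snpchar.errors import ConfigError
from snpchar.synthetic_data import sim_config_from_yaml, write_dataset

from _oracles import translate_codon


STOPS = {"TAA", "TAG", "TGA"}


class TestConfig:
    def test_invalid_ranges_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(codon_length_range=(10, 5))
        with pytest.raises(ConfigError):
            SimConfig(codon_length_range=(1, 1))
        with pytest.raises(ConfigError):
            SimConfig(target_nonsyn_fraction=1.5)
        with pytest.raises(ConfigError):
            SimConfig(n_genes=0)

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "sim.yaml"
        p.write_text(
            "seed: 9\nn_genes: 4\ncodon_length_range: [30, 40]\n"
            "target_nonsyn_fraction: 0.5\nn_homologs: 6\n"
        )
        cfg = sim_config_from_yaml(p)
        assert cfg == SimConfig(seed=9, n_genes=4, codon_length_range=(30, 40),
                                target_nonsyn_fraction=0.5, n_homologs=6)


class TestOrfGeneration:
    def test_structure_and_determinism(self):
        cfg = SimConfig(seed=1, n_genes=5)
        orfs = generate_orfs(cfg)
        assert len(orfs) == 5
        again = generate_orfs(cfg)
        assert {g: o.sequence for g, o in orfs.items()} == \
               {g: o.sequence for g, o in again.items()}

    def test_minimal_orfs_are_start_plus_stop(self):
        cfg = SimConfig(seed=3, n_genes=10, codon_length_range=(2, 2))
        for orf in generate_orfs(cfg).values():
            assert len(orf) == 6
            assert orf.sequence.startswith("ATG")
            assert orf.sequence[3:] in STOPS

    def test_no_internal_stops_across_many_orfs(self):
        cfg = SimConfig(seed=5, n_genes=1000, codon_length_range=(10, 30))
        for orf in generate_orfs(cfg).values():
            seq = orf.sequence
            assert len(seq) % 3 == 0
            codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
            assert codons[0] == "ATG"
            assert codons[-1] in STOPS
            assert not any(c in STOPS for c in codons[1:-1])
            lo, hi = cfg.codon_length_range
            assert lo <= len(codons) <= hi


class TestSnpSpiking:
    def test_all_nonsyn_boundary(self):
        cfg = SimConfig(seed=7, n_genes=5, target_nonsyn_fraction=1.0)
        orfs = generate_orfs(cfg)
        _, truth = spike_snps(orfs, cfg)
        assert truth
        assert all(t.effect_class != SILENT for t in truth)

    def test_all_silent_boundary(self):
        cfg = SimConfig(seed=7, n_genes=5, target_nonsyn_fraction=0.0)
        orfs = generate_orfs(cfg)
        _, truth = spike_snps(orfs, cfg)
        assert truth
        assert all(t.effect_class == SILENT for t in truth)

    def test_realized_fraction_near_target(self):
        cfg = SimConfig(seed=11, n_genes=40, codon_length_range=(100, 200),
                        target_nonsyn_fraction=0.233)
        orfs = generate_orfs(cfg)
        _, truth = spike_snps(orfs, cfg, n_total=1000)
        assert len(truth) == 1000
        frac = sum(t.effect_class != SILENT for t in truth) / 1000
        assert abs(frac - 0.233) <= 0.03

    def test_positions_unique_per_gene_and_ref_matches_orf(self):
        cfg = SimConfig(seed=13, n_genes=10)
        orfs = generate_orfs(cfg)
        _, truth = spike_snps(orfs, cfg)
        seen = set()
        for t in truth:
            key = (t.record.gene_id, t.record.position)
            assert key not in seen
            seen.add(key)
            assert orfs[t.record.gene_id].sequence[t.record.position - 1] == \
                t.record.ref_base

    def test_truth_labels_match_classifier(self, small_dataset):
        effects, failures = classify_all(
            small_dataset.orfs, [t.record for t in small_dataset.truth]
        )
        assert failures == []
        for eff, t in zip(effects, small_dataset.truth):
            assert eff.effect_class == t.effect_class

    def test_pass_flags_agree_with_filter(self, small_dataset):
        thr = FilterThresholds()
        for cand, t in zip(small_dataset.candidates, small_dataset.truth):
            assert (not thr.violations(cand)) == t.passes_filter

    def test_capacity_error_when_orfs_too_small(self):
        cfg = SimConfig(seed=17, n_genes=2, codon_length_range=(2, 2))
        orfs = generate_orfs(cfg)
        from snpchar.errors import CapacityError
        with pytest.raises(CapacityError):
            spike_snps(orfs, cfg, n_total=100)


class TestAlignments:
    def test_full_conservation_copies_reference(self):
        cfg = SimConfig(seed=19, n_genes=1, column_conservation=1.0,
                        gap_fraction=0.0)
        orf = next(iter(generate_orfs(cfg).values()))
        aln = generate_homolog_alignment(orf, cfg)
        assert all(row == aln.reference_row for _, row in aln.homolog_rows())
        ref_aa = aln.reference_row[4]
        variant = "W" if ref_aa != "W" else "Y"
        s = conservation_stats(aln, 5, ref_aa, variant)
        assert s.conservation_distance == 1.0

    def test_all_variant_override_gives_minus_one(self):
        cfg = SimConfig(seed=19, n_genes=1, gap_fraction=0.0)
        orf = next(iter(generate_orfs(cfg).values()))
        protein_pos = 5
        ref_res = generate_homolog_alignment(orf, cfg).reference_row[protein_pos - 1]
        variant = "W" if ref_res != "W" else "Y"
        aln = generate_homolog_alignment(
            orf, cfg, overrides={protein_pos: ("all_variant", variant)}
        )
        s = conservation_stats(aln, protein_pos, ref_res, variant)
        assert s.conservation_distance == -1.0

    def test_reference_row_is_translated_orf(self):
        cfg = SimConfig(seed=23, n_genes=1)
        orf = next(iter(generate_orfs(cfg).values()))
        aln = generate_homolog_alignment(orf, cfg)
        seq = orf.sequence
        protein = "".join(
            translate_codon(seq[i:i + 3]) for i in range(0, len(seq) - 3, 3)
        )
        assert aln.reference_row == protein

    def test_match_fraction_concentrates_at_conservation_level(self):
        cfg = SimConfig(seed=29, n_genes=1, codon_length_range=(502, 502),
                        column_conservation=0.5, gap_fraction=0.0,
                        n_homologs=10)
        orf = next(iter(generate_orfs(cfg).values()))
        aln = generate_homolog_alignment(orf, cfg)
        ref = aln.reference_row
        matches = total = 0
        for _, row in aln.homolog_rows():
            matches += sum(a == b for a, b in zip(row, ref))
            total += len(ref)
        frac = matches / total
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / total)


class TestDatasets:
    def test_written_fixture_is_byte_identical_across_runs(self, tmp_path):
        cfg = SimConfig(seed=31, n_genes=4, codon_length_range=(20, 40))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(generate_dataset(cfg), d1)
        write_dataset(generate_dataset(cfg), d2)
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_annotation_sizes_within_range(self, small_dataset):
        cfg = small_dataset.config
        lo, hi = cfg.genes_per_term_range
        assert len(small_dataset.annotations) == cfg.annotation_terms
        gene_ids = set(small_dataset.orfs)
        for ann in small_dataset.annotations:
            assert lo <= len(ann.genes) <= hi
            assert ann.genes <= gene_ids
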