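import numpy as np
import pytest

from snpchar import (
    OrfSequence,
    SnpRecord,
    classify_all,
    classify_snp_effect,
    is_nonsynonymous,
    map_genomic_to_orf,
)
from snpchar.codon_effects import MISSENSE, NONSENSE, SILENT, STOP_LOSS
from snpchar.errors import (
    FrameError,
    IndeterminateCodonError,
    LookupError_,
    RefBaseMismatchError,
)

from _oracles import (
    all_single_base_substitutions,
    classify_pair,
    orf_to_genomic,
    translate_codon,
)
from conftest import make_orf_with_codon


class TestClassifySingle:
    def test_premature_stop_worked_example(self):
        # 729-nt ORF with codon 98 = TAT; the T->G change at nt 294 turns
        # the tyrosine codon into the amber stop TAG
        orf = make_orf_with_codon("PAD1", 243, "TAT", 98)
        eff = classify_snp_effect(orf, SnpRecord("PAD1", 294, "T", "G"))
        assert eff.codon_index == 98
        assert eff.codon_offset == 3
        assert (eff.ref_codon, eff.alt_codon) == ("TAT", "TAG")
        assert (eff.ref_aa, eff.alt_aa) == ("Y", "*")
        assert eff.effect_class == NONSENSE
        assert is_nonsynonymous(eff.effect_class)

    def test_third_position_wobble_is_silent(self):
        orf = make_orf_with_codon("G1", 3, "GCT", 1)
        # codon 1 replaced by GCT, so the ORF need not start ATG here
        eff = classify_snp_effect(orf, SnpRecord("G1", 3, "T", "C"))
        assert (eff.ref_codon, eff.alt_codon) == ("GCT", "GCC")
        assert eff.ref_aa == eff.alt_aa == "A"
        assert eff.effect_class == SILENT

    def test_exhaustive_576_cases_match_brute_force(self):
        for ref_codon, offset, alt in all_single_base_substitutions():
            orf = make_orf_with_codon("G", 4, ref_codon, 2)
            snp = SnpRecord("G", 3 + offset + 1, ref_codon[offset], alt)
            eff = classify_snp_effect(orf, snp)
            alt_codon = ref_codon[:offset] + alt + ref_codon[offset + 1:]
            assert eff.alt_codon == alt_codon
            assert eff.ref_aa == translate_codon(ref_codon)
            assert eff.alt_aa == translate_codon(alt_codon)
            assert eff.effect_class == classify_pair(ref_codon, alt_codon)

    def test_silent_fraction_matches_enumeration(self):
        ours = oracle = 0
        for ref_codon, offset, alt in all_single_base_substitutions():
            orf = make_orf_with_codon("G", 4, ref_codon, 2)
            snp = SnpRecord("G", 3 + offset + 1, ref_codon[offset], alt)
            if classify_snp_effect(orf, snp).effect_class == SILENT:
                ours += 1
            alt_codon = ref_codon[:offset] + alt + ref_codon[offset + 1:]
            if classify_pair(ref_codon, alt_codon) == SILENT:
                oracle += 1
        assert ours == oracle

    def test_mutating_ref_codon_reproduces_alt_codon(self):
        orf = make_orf_with_codon("G", 5, "CAA", 3)
        eff = classify_snp_effect(orf, SnpRecord("G", 7, "C", "T"))
        i = eff.codon_offset - 1
        assert eff.ref_codon[:i] + "T" + eff.ref_codon[i + 1:] == eff.alt_codon

    def test_stop_to_stop_is_silent(self):
        orf = make_orf_with_codon("G", 3, "TAA", 3)
        eff = classify_snp_effect(orf, SnpRecord("G", 9, "A", "G"))  # TAA->TAG
        assert eff.effect_class == SILENT

    def test_stop_loss_detected(self):
        orf = make_orf_with_codon("G", 3, "TAA", 3)
        eff = classify_snp_effect(orf, SnpRecord("G", 8, "A", "C"))  # TAA->TCA
        assert eff.effect_class == STOP_LOSS

    def test_ref_base_mismatch(self):
        orf = make_orf_with_codon("G", 3, "GCT", 2)
        with pytest.raises(RefBaseMismatchError, match="G:4"):
            classify_snp_effect(orf, SnpRecord("G", 4, "A", "T"))

    def test_frame_error(self):
        orf = OrfSequence("G", "ATGAA")
        with pytest.raises(FrameError):
            classify_snp_effect(orf, SnpRecord("G", 1, "A", "G"))

    def test_indeterminate_codon(self):
        orf = OrfSequence("G", "ATGANATAA")
        with pytest.raises(IndeterminateCodonError):
            classify_snp_effect(orf, SnpRecord("G", 4, "A", "G"))


class TestClassifyBatch:
    def test_order_preserved(self):
        orf = make_orf_with_codon("G", 4, "GCT", 2)
        snps = [SnpRecord("G", 6, "T", "C"),   # silent wobble
                SnpRecord("G", 4, "G", "A")]   # missense GCT->ACT
        effects, failures = classify_all({"G": orf}, snps)
        assert failures == []
        assert [e.effect_class for e in effects] == [SILENT, MISSENSE]

    def test_empty_input(self):
        assert classify_all({}, []) == ([], [])

    def test_permutation_equivariance(self):
        orf = make_orf_with_codon("G", 10, "GCT", 5)
        rng = np.random.default_rng(2)
        snps = []
        for pos in range(4, 28):
            ref = orf.sequence[pos - 1]
            alt = next(b for b in "ACGT" if b != ref)
            snps.append(SnpRecord("G", pos, ref, alt))
        perm = rng.permutation(len(snps))
        base, _ = classify_all({"G": orf}, snps)
        shuffled, _ = classify_all({"G": orf}, [snps[i] for i in perm])
        assert shuffled == [base[i] for i in perm]

    def test_lenient_mode_collects_failures(self):
        orf = make_orf_with_codon("G", 3, "GCT", 2)
        snps = [SnpRecord("MISSING", 1, "A", "G"),
                SnpRecord("G", 6, "T", "C")]
        effects, failures = classify_all({"G": orf}, snps)
        assert len(effects) == 1 and len(failures) == 1
        assert isinstance(failures[0][1], LookupError_)

    def test_strict_mode_raises(self):
        with pytest.raises(LookupError_):
            classify_all({}, [SnpRecord("X", 1, "A", "G")], strict=True)

    def test_generator_truth_recovered(self, small_dataset):
        effects, failures = classify_all(
            small_dataset.orfs, [t.record for t in small_dataset.truth]
        )
        assert failures == []
        assert [e.effect_class for e in effects] == [
            t.effect_class for t in small_dataset.truth
        ]


class TestGenomicMapping:
    def test_plus_strand_identity_at_start(self):
        assert map_genomic_to_orf(100, 100, 200, "+", "A", "G") == (1, "A", "G")

    def test_minus_strand_complements_and_reverses(self):
        assert map_genomic_to_orf(100, 100, 102, "-", "A", "G") == (3, "T", "C")

    def test_out_of_span_rejected(self):
        from snpchar.errors import RangeError
        with pytest.raises(RangeError):
            map_genomic_to_orf(99, 100, 200, "+", "A", "G")

    def test_round_trip_against_independent_inverse(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            start = int(rng.integers(1, 10_000))
            length = int(rng.integers(1, 5_000))
            end = start + length - 1
            pos = int(rng.integers(start, end + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            orf_pos, _, _ = map_genomic_to_orf(pos, start, end, strand, "A", "G")
            assert orf_to_genomic(orf_pos, start, end, strand) == pos
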