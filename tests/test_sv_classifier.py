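import numpy as np
import pytest

from fgfr2trunc.gene_model import GeneSet, annotate_breakend, compute_exon_phases
from fgfr2trunc.sv_classifier import (
    REType,
    classify_re,
    compute_allele_frequency,
    call_insertion_hits,
    normalize_clonality,
    select_backbone,
    sliding_window_density,
)
from conftest import make_random_gene


def _mid(iv):
    return (iv[0] + iv[1]) // 2


def intron_iv(model, k):
    a, b = model.exons[k - 1], model.exons[k]
    return (a[1], b[0]) if model.strand == "+" else (b[1], a[0])


def be(models, pos, orient="sense", chrom="chrT"):
    return annotate_breakend(chrom, pos, orient, models)


class TestBackbone:
    def test_longer_protein_wins(self, models):
        assert select_backbone(models["FGFR2"], models["BICC1L"]) == "BICC1L"
        assert select_backbone(models["FGFR2"], models["SHORTP"]) == "FGFR2"

    def test_sole_coding_partner_wins(self, models):
        assert select_backbone(models["FGFR2"], models["LNC1"]) == "FGFR2"

    def test_tie_breaks_lexicographically(self, models):
        a = make_random_gene(np.random.default_rng(0), "A")
        b = a.__class__(**{**a.__dict__, "gene_id": "B"})
        assert select_backbone(a, b) == "A"


class TestClassifyRE:
    def test_in_frame_fusion_compatible_intronic_phases(self, models, fgfr2):
        # FGFR2 E17 ends at phase 1; BICC1L exon 2 starts at phase 1
        a = be(models, _mid(intron_iv(fgfr2, 17)))
        b = be(models, _mid(intron_iv(models["BICC1L"], 1)))
        call = classify_re(a, b, models)
        assert call.re_type is REType.IN_FRAME_FUSION
        assert call.backbone_gene == "BICC1L"  # longer protein

    def test_in_frame_fusion_minus_strand_partner(self, models, fgfr2):
        a = be(models, _mid(intron_iv(fgfr2, 17)))
        b = be(models, _mid(intron_iv(models["MINUSP"], 1)))
        assert classify_re(a, b, models).re_type is REType.IN_FRAME_FUSION

    def test_frame_unknown_incompatible_phases(self, models, fgfr2):
        a = be(models, _mid(intron_iv(fgfr2, 17)))       # phase 1
        b = be(models, _mid(intron_iv(models["BICC1L"], 2)))  # exon 3 starts phase 2
        assert classify_re(a, b, models).re_type is REType.FRAME_UNKNOWN

    def test_intergenic_partner(self, models, fgfr2):
        a = be(models, _mid(intron_iv(fgfr2, 17)))
        b = be(models, 750_000)
        assert classify_re(a, b, models).re_type is REType.INTERGENIC_SPACE

    def test_noncoding_gene_partner_counts_as_intergenic(self, models, fgfr2):
        a = be(models, _mid(intron_iv(fgfr2, 17)))
        b = be(models, 600_100)  # inside LNC1 exon
        assert classify_re(a, b, models).re_type is REType.INTERGENIC_SPACE

    def test_internal_both_breakends_in_gene(self, models, fgfr2):
        a = be(models, _mid(intron_iv(fgfr2, 17)))
        b = be(models, _mid(intron_iv(fgfr2, 3)))
        assert classify_re(a, b, models).re_type is REType.INTERNAL

    def test_out_of_strand_antisense_partner(self, models, fgfr2):
        a = be(models, _mid(intron_iv(fgfr2, 17)))
        b = be(models, _mid(intron_iv(models["BICC1L"], 1)), "antisense")
        assert classify_re(a, b, models).re_type is REType.OUT_OF_STRAND

    def test_unresolved_antisense_upstream(self, models, fgfr2):
        a = be(models, _mid(intron_iv(fgfr2, 17)), "antisense")
        b = be(models, _mid(intron_iv(models["BICC1L"], 1)))
        assert classify_re(a, b, models).re_type is REType.UNRESOLVED

    def test_unresolved_single_breakend(self, models, fgfr2):
        a = be(models, _mid(intron_iv(fgfr2, 17)))
        assert classify_re(a, None, models).re_type is REType.UNRESOLVED
        assert classify_re(a, a, models).re_type is REType.UNRESOLVED

    def test_order_insensitivity(self, models, fgfr2):
        a = be(models, _mid(intron_iv(fgfr2, 17)))
        for partner_pos, orient in [
            (_mid(intron_iv(models["BICC1L"], 1)), "sense"),
            (_mid(intron_iv(models["BICC1L"], 2)), "sense"),
            (750_000, "sense"),
        ]:
            b = be(models, partner_pos, orient)
            c1 = classify_re(a, b, models)
            c2 = classify_re(b, a, models)
            assert c1.re_type is c2.re_type
            assert c1.breakend_a == c2.breakend_a

    def test_totality_every_pair_gets_one_type(self, models, fgfr2):
        rng = np.random.default_rng(11)
        positions = [int(rng.integers(5_000, 800_000)) for _ in range(200)]
        for pos in positions:
            a = be(models, _mid(intron_iv(fgfr2, 17)))
            b = be(models, pos, "sense" if rng.random() < 0.8 else "antisense")
            call = classify_re(a, b, models)
            assert call.re_type in REType


class TestExonicFrame:
    def test_exonic_exonic_in_frame_and_shifted(self, models, fgfr2):
        """Exonic junctions: equal codon phase at both breaks is in frame;
        shifting one side by a single base breaks the frame."""
        bicc = models["BICC1L"]
        ph_f = {p.exon_index: p for p in compute_exon_phases(fgfr2)}
        ph_b = {p.exon_index: p for p in compute_exon_phases(bicc)}
        # phase at FGFR2 E17 position s+off = (start_phase + off) % 3
        e17 = fgfr2.exons[16]
        b3 = bicc.exons[2]
        off_a = (3 - ph_f[17].start_phase) % 3 + 9   # phase 0 break
        off_b = (3 - ph_b[3].start_phase) % 3 + 9    # phase 0 break
        a = be(models, e17[0] + off_a)
        b = be(models, b3[0] + off_b)
        assert classify_re(a, b, models).re_type is REType.IN_FRAME_FUSION
        b_shift = be(models, b3[0] + off_b + 1)
        assert classify_re(a, b_shift, models).re_type is REType.FRAME_UNKNOWN


class TestFrameOracle:
    """classify_re's intronic in-frame decision versus a brute-force oracle
    that concatenates per-exon CDS strings and checks codon continuity of
    the downstream fragment within the fused sequence."""

    @staticmethod
    def oracle_in_frame(gene_a, k, gene_b, j):
        up = "".join("A" * (e - s) for s, e in gene_a.exons[:k])
        b_before = "".join("B" * (e - s) for s, e in gene_b.exons[:j])
        return (len(up) - len(b_before)) % 3 == 0

    def run_pairs(self, n_pairs, seed):
        rng = np.random.default_rng(seed)
        mismatches = 0
        for i in range(n_pairs):
            ga = make_random_gene(rng, "GOI", start=10_000,
                                  strand="+" if rng.random() < 0.7 else "-")
            gb = make_random_gene(rng, "PARTNER", start=500_000,
                                  strand="+" if rng.random() < 0.7 else "-")
            models = GeneSet([ga, gb])
            k = int(rng.integers(1, ga.n_exons))
            j = int(rng.integers(1, gb.n_exons))
            pa = _mid(intron_iv(ga, k))
            pb = _mid(intron_iv(gb, j))
            a = annotate_breakend("chrR", pa, "sense", models)
            b = annotate_breakend("chrR", pb, "sense", models)
            assert a.context == ("intron", "GOI", k)
            assert b.context == ("intron", "PARTNER", j)
            call = classify_re(a, b, models, gene_of_interest="GOI")
            got = call.re_type is REType.IN_FRAME_FUSION
            expect = self.oracle_in_frame(ga, k, gb, j)
            mismatches += got != expect
        return mismatches

    def test_frame_decisions_match_oracle(self):
        assert self.run_pairs(200, seed=3) == 0


class TestAlleleFrequency:
    def make_truncating_call(self, models, fgfr2, ploidy, gene_cn):
        a = be(models, _mid(intron_iv(fgfr2, 17)))
        b = be(models, _mid(intron_iv(models["BICC1L"], 1)))
        call = classify_re(a, b, models)
        return compute_allele_frequency(
            call, gene_cn, junction_ploidy=ploidy, gene_of_interest_model=fgfr2
        )

    def test_half_frequency_is_truncating(self, models, fgfr2):
        call = self.make_truncating_call(models, fgfr2, 1.0, 2.0)
        assert call.allele_frequency == 0.5
        assert call.e18_truncating

    def test_low_frequency_is_not(self, models, fgfr2):
        call = self.make_truncating_call(models, fgfr2, 0.2, 2.0)
        assert call.allele_frequency == pytest.approx(0.1)
        assert not call.e18_truncating

    def test_threshold_is_strict(self, models, fgfr2):
        call = self.make_truncating_call(models, fgfr2, 0.3, 2.0)
        assert call.allele_frequency == pytest.approx(0.15)
        assert not call.e18_truncating  # 0.15 does not exceed 0.15

    def test_frequency_clamped_to_one(self, models, fgfr2):
        call = self.make_truncating_call(models, fgfr2, 5.0, 4.0)
        assert call.allele_frequency == 1.0

    def test_nonpositive_cn_rejected(self, models, fgfr2):
        with pytest.raises(ValueError):
            self.make_truncating_call(models, fgfr2, 1.0, 0.0)

    def test_breakend_outside_last_intron_not_truncating(self, models, fgfr2):
        a = be(models, _mid(intron_iv(fgfr2, 3)))
        b = be(models, 750_000)
        call = classify_re(a, b, models)
        call = compute_allele_frequency(
            call, 2.0, junction_ploidy=1.0, gene_of_interest_model=fgfr2
        )
        assert not call.e18_truncating


class TestClonality:
    def test_hand_computed_normalisation(self):
        assert normalize_clonality([40, 10, 8]) == pytest.approx([1.0, 0.25, 0.2])
        assert call_insertion_hits([40, 10, 8]) == [True, True, False]

    def test_threshold_is_inclusive(self):
        assert call_insertion_hits([40, 10]) == [True, True]      # 0.25 >= 0.25
        assert call_insertion_hits([40, 9]) == [True, False]      # 0.225 < 0.25

    def test_single_score_fully_clonal(self):
        assert normalize_clonality([7]) == [1.0]

    def test_all_zero_scores_rejected(self):
        with pytest.raises(ValueError):
            normalize_clonality([0.0, 0.0])


class TestSlidingWindowDensity:
    def test_two_positions_within_one_window(self):
        track, offset = sliding_window_density([1000, 1100], window=500)
        assert track[1050 - offset] == 2

    def test_empty_and_singleton(self):
        track, _ = sliding_window_density([], window=500)
        assert track.sum() == 0
        track, _ = sliding_window_density([5000], window=500)
        assert track.max() == 1

    def test_tiling_conserves_total_count(self):
        rng = np.random.default_rng(5)
        positions = sorted(rng.integers(0, 50_000, size=200).tolist())
        window = 500
        track, offset = sliding_window_density(positions, window=window)
        centers = np.arange(offset + window // 2, offset + len(track) - window, window)
        assert track[centers - offset].sum() == len(positions)
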