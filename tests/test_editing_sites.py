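"""Variant tallies, binomial significance, classification, SNP calling,
sample combination and cross-species matching."""

import math

import pytest

from conftest import binomial_tail
from miredit.editing_sites import (
    EditingConfig,
    MESite,
    SNPRecord,
    adjust_and_filter,
    call_snps,
    classify_site,
    combine_samples,
    match_conserved_sites,
    normalize_family_key,
    sites_from_tallies,
    tally_variants,
)
from miredit.editing_sites import test_site as site_p_value
from miredit.mirna_discovery import Precursor
from miredit.read_alignment import PrecursorAlignment
from miredit.sequence_io import GenomicLocus, SmallRead


def _prec(seq="ACGT" * 20, pid="prec", strand="+", matures=None):
    return Precursor(
        id=pid,
        sequence=seq,
        locus=GenomicLocus("chr1", 1001, 1000 + len(seq), strand, id=pid),
        matures=matures or {"5p": (3, 24)},
    )


def _aln(read_seq, count, offset, mismatches=(), tail="", pid="prec"):
    return PrecursorAlignment(
        read=SmallRead(read_seq, count),
        precursor_id=pid,
        offset=offset,
        mismatches=tuple(mismatches),
        soft_tail=tail,
    )


class TestTallyVariants:
    def test_support_and_depth_arithmetic(self):
        prec = _prec()
        ref_read = prec.sequence[2:24]
        alt_read = list(ref_read)
        alt_read[7] = "G" if ref_read[7] != "G" else "T"
        alt_nt = alt_read[7]
        alns = [
            _aln(ref_read, 90, 3),
            _aln("".join(alt_read), 10, 3,
                 mismatches=[(10, ref_read[7], alt_nt)]),
        ]
        t = tally_variants(alns, prec)
        assert t[10].depth == 100
        assert t[10].alts == {alt_nt: 10}

    def test_cross_map_weights_scale_support(self):
        prec = _prec()
        ref_read = prec.sequence[2:24]
        alt_read = ref_read[:7] + "N"  # placeholder, rebuilt below
        alt = "G" if ref_read[7] != "G" else "T"
        alt_read = ref_read[:7] + alt + ref_read[8:]
        alns = [_aln(alt_read, 10, 3, mismatches=[(10, ref_read[7], alt)])]
        t = tally_variants(alns, prec, weights={alt_read: 0.5})
        assert t[10].alts[alt] == pytest.approx(5.0)
        assert t[10].depth == pytest.approx(5.0)

    def test_no_coverage_no_tally(self):
        assert tally_variants([], _prec()) == {}

    def test_weighted_conservation(self):
        """ref count + alt support equals depth at every position."""
        prec = _prec()
        ref_read = prec.sequence[0:22]
        alt = "C" if prec.sequence[5] != "C" else "A"
        alt_read = ref_read[:5] + alt + ref_read[6:]
        alns = [
            _aln(ref_read, 13, 1),
            _aln(alt_read, 4, 1, mismatches=[(6, ref_read[5], alt)]),
        ]
        t = tally_variants(alns, prec, weights={ref_read: 0.7, alt_read: 0.9})
        for pos, tally in t.items():
            alt_sum = sum(tally.alts.values()) + sum(tally.tail_alts.values())
            assert alt_sum <= tally.depth + 1e-9


class TestTestSite:
    def test_zero_support_is_one(self):
        assert site_p_value(0, 100) == 1.0

    def test_matches_direct_summation(self):
        cfg = EditingConfig(per_base_error=1 / 3000)
        for n in range(1, 31):
            for k in range(0, n + 1):
                got = site_p_value(k, n, cfg)
                want = binomial_tail(k, n, 1 / 3000)
                assert abs(got - want) <= 1e-12, (k, n)

    def test_large_support_is_extreme(self):
        # exact tail for n=200, k=10 under the Q30 error null is ~3.6e-19
        assert site_p_value(10, 200) < 1e-18

    def test_fractional_support_rounded_up(self):
        assert site_p_value(9.5, 100) == site_p_value(10, 100)

    def test_support_above_depth_rejected(self):
        with pytest.raises(ValueError):
            site_p_value(11, 10)


class TestAdjustAndFilter:
    def _site(self, support, depth, p):
        return MESite(
            precursor_id="p", position=10, ref="A", alt="G",
            support=support, depth=depth, p_value=p,
        )

    def test_boundary_site_kept(self):
        kept = adjust_and_filter([self._site(10, 200, 1e-30)])
        assert len(kept) == 1

    def test_low_support_dropped(self):
        assert adjust_and_filter([self._site(9, 45, 1e-30)]) == []

    def test_low_level_dropped(self):
        assert adjust_and_filter([self._site(50, 1250, 1e-30)]) == []

    def test_corrected_p_above_alpha_dropped(self):
        assert adjust_and_filter([self._site(10, 100, 0.06)]) == []

    def test_bh_adjustment_is_monotone_in_rank(self):
        sites = [self._site(20, 100, p) for p in (1e-10, 0.01, 0.04, 0.9)]
        kept = adjust_and_filter(sites)
        # BH with m=4: adjusted p's 4e-10, 0.02, 0.053, 0.9
        assert [s.p_value for s in kept] == [1e-10, 0.01]


class TestClassifySite:
    def _site(self, pos, ref, alt, is_tail=False):
        return MESite(
            precursor_id="prec", position=pos, ref=ref, alt=alt,
            support=20, depth=100, is_tail=is_tail,
        )

    def test_a_to_g_in_mature_is_a_to_i(self):
        prec = _prec()
        s = classify_site(self._site(8, "A", "G"), prec)
        assert s.category == "A-to-I"
        assert s.mature_position == 6

    def test_c_to_t_is_c_to_u(self):
        s = classify_site(self._site(10, "C", "T"), _prec())
        assert s.category == "C-to-U"

    def test_tail_categories_by_nucleotide(self):
        prec = _prec()
        assert classify_site(self._site(25, "C", "A", True), prec).category == "3'-A"
        assert classify_site(self._site(25, "C", "T", True), prec).category == "3'-U"
        assert classify_site(self._site(25, "C", "G", True), prec).category == "3'-Other"

    def test_five_prime_site(self):
        s = classify_site(self._site(3, "A", "C"), _prec())
        assert s.category == "5' site"

    def test_g_to_t_is_other_with_subtype(self):
        s = classify_site(self._site(11, "G", "T"), _prec())
        assert s.category == "Other"
        assert s.subtype == "G-to-U"

    def test_majority_weight_elsewhere_is_pseudo(self):
        s = classify_site(self._site(8, "A", "G"), _prec(),
                          cross_weight_elsewhere=0.6)
        assert s.category == "Pseudo"

    def test_every_site_gets_exactly_one_category(self):
        from miredit.editing_sites import CATEGORIES

        prec = _prec()
        for pos in range(1, 40):
            for ref, alt in (("A", "G"), ("C", "T"), ("G", "A")):
                s = classify_site(self._site(pos, ref, alt), prec)
                assert s.category in CATEGORIES


class TestCallSnps:
    def _study_sites(self, level, pos=10, ref="G", alt="A"):
        support = level * 100
        return [
            MESite(precursor_id="prec", position=pos, ref=ref, alt=alt,
                   support=support, depth=100, sample_id="s1"),
            MESite(precursor_id="prec", position=pos, ref=ref, alt=alt,
                   support=40, depth=100, sample_id="s2"),
        ]

    def test_full_level_with_matching_record_is_snp(self):
        prec = _prec()
        snps = [SNPRecord("chr1", 1010, "G", "A")]
        out = call_snps(self._study_sites(1.0), snps, {"prec": prec})
        assert out[0].category == "SNP" and out[1].category == "SNP"

    def test_97_percent_level_is_not_snp(self):
        prec = _prec()
        snps = [SNPRecord("chr1", 1010, "G", "A")]
        out = call_snps(self._study_sites(0.97), snps, {"prec": prec})
        assert all(s.category != "SNP" for s in out)

    def test_allele_mismatch_is_not_snp(self):
        prec = _prec()
        snps = [SNPRecord("chr1", 1010, "G", "C")]
        out = call_snps(self._study_sites(1.0), snps, {"prec": prec})
        assert all(s.category != "SNP" for s in out)

    def test_minus_strand_alleles_complemented(self):
        prec = _prec(strand="-")
        # precursor position 10 -> genomic end - 9; alleles complemented
        gpos = prec.locus.end - 9
        snps = [SNPRecord("chr1", gpos, "C", "T")]
        out = call_snps(self._study_sites(1.0), snps, {"prec": prec})
        assert out[0].category == "SNP"

    def test_missing_locus_leaves_site_unchanged(self):
        prec = Precursor(id="prec", sequence="ACGT" * 20)
        snps = [SNPRecord("chr1", 1010, "G", "A")]
        out = call_snps(self._study_sites(1.0), snps, {"prec": prec})
        assert all(s.category != "SNP" for s in out)


class TestCombineSamples:
    def _site(self, sample, level=0.5):
        return MESite(
            precursor_id="p", position=5, ref="A", alt="G",
            support=level * 100, depth=100, sample_id=sample,
        )

    def test_same_site_two_samples_one_row(self):
        combined = combine_samples(
            [("s1", [self._site("s1", 0.2)]), ("s2", [self._site("s2", 0.6)])]
        )
        assert combined.levels.shape == (1, 2)
        assert combined.info.iloc[0]["n_samples_detected"] == 2

    def test_significant_in_one_sample_flagged(self):
        combined = combine_samples(
            [("s1", [self._site("s1")]), ("s2", [self._site("s2")]),
             ("s3", [self._site("s3")])],
            significant_ids={"s1": {"p_5_A_g"}, "s2": set(), "s3": set()},
        )
        assert combined.info.iloc[0]["n_samples_significant"] == 1

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError):
            combine_samples([("s1", []), ("s1", [])])

    def test_empty_input_empty_matrix(self):
        combined = combine_samples([])
        assert combined.levels.empty and combined.info.empty


class TestMatchConservedSites:
    def _site(self, pid, mat_pos, ref="A", alt="G"):
        return MESite(
            precursor_id=pid, position=40, ref=ref, alt=alt,
            support=10, depth=50, mature_position=mat_pos,
        )

    def test_family_key_normalization(self):
        assert normalize_family_key("mml-mir-376a-1") == "mir-376a"
        assert normalize_family_key("hsa-mir-376a-2") == "mir-376a"
        assert normalize_family_key("mml-let-7e") == "let-7e"

    def test_conserved_site_matches(self):
        a = self._site("mml-mir-376c", 6)
        b = self._site("hsa-mir-376c", 6)
        assert match_conserved_sites([a], [b]) == [(a, b)]

    def test_different_substitution_unmatched(self):
        a = self._site("mml-mir-376c", 6, "A", "G")
        b = self._site("hsa-mir-376c", 6, "C", "T")
        assert match_conserved_sites([a], [b]) == []

    def test_different_position_unmatched(self):
        a = self._site("mml-mir-376c", 6)
        b = self._site("hsa-mir-376c", 7)
        assert match_conserved_sites([a], [b]) == []

    def test_no_mature_position_unmatched(self):
        a = self._site("mml-mir-376c", None)
        b = self._site("hsa-mir-376c", 6)
        assert match_conserved_sites([a], [b]) == []


class TestSiteId:
    def test_id_format_matches_convention(self):
        s = MESite(precursor_id="mml-mir-376c", position=48, ref="A",
                   alt="G", support=10, depth=20)
        assert s.site_id == "mml-mir-376c_48_A_g"

    def test_rna_alphabet_in_id(self):
        s = MESite(precursor_id="mml-mir-3173", position=49, ref="T",
                   alt="C", support=10, depth=10)
        assert s.site_id == "mml-mir-3173_49_U_c"
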