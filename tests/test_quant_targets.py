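"""Expression quantification, seed-target prediction and enrichment."""

import math
import random

import pytest
from scipy import stats

from miredit.editing_sites import MESite
from miredit.quant_targets import (
    RPTM_SCALE,
    apply_edit,
    compare_target_sets,
    compute_rptm,
    enrich_sets,
    predict_targets,
    select_expressed,
)


class TestComputeRptm:
    def test_definitional_value(self):
        recs = compute_rptm({"m1": 5.0}, "s", total=10_000_000)
        assert recs[0].rptm == pytest.approx(5.0)

    def test_zero_count_zero_rptm(self):
        recs = compute_rptm({"m1": 0.0, "m2": 10.0}, "s")
        assert {r.mature_id: r.rptm for r in recs}["m1"] == 0.0

    def test_scale_invariance(self):
        a = compute_rptm({"m1": 3.0, "m2": 7.0}, "s")
        b = compute_rptm({"m1": 6.0, "m2": 14.0}, "s")
        assert [r.rptm for r in a] == pytest.approx([r.rptm for r in b])

    def test_self_normalized_totals(self):
        recs = compute_rptm({"m1": 3.0, "m2": 7.0, "m3": 1.0}, "s")
        assert sum(r.rptm for r in recs) == pytest.approx(RPTM_SCALE)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            compute_rptm({"m1": 0.0}, "s")


class TestSelectExpressed:
    def _records(self, values_by_mature):
        return [
            r
            for mid, vals in values_by_mature.items()
            for r in (
                compute_rptm({mid: v}, f"s{i}", total=RPTM_SCALE)
                for i, v in enumerate(vals)
            )
            for r in [r[0]]
        ]

    def test_constant_expression_dropped_by_sd_clause(self):
        recs = self._records({"m": [100.0, 100.0, 100.0]})
        assert select_expressed(recs) == set()

    def test_low_mean_dropped(self):
        recs = self._records({"m": [1.9, 4.9, 7.9]})
        assert select_expressed(recs) == set()

    def test_boundary_kept(self):
        recs = self._records({"m": [4.0, 5.0, 6.0]})  # mean 5.0, sd 1.0
        assert select_expressed(recs) == {"m"}

    def test_single_sample_rejected(self):
        recs = self._records({"m": [10.0]})
        with pytest.raises(ValueError):
            select_expressed(recs)


class TestApplyEdit:
    def _site(self, pos, ref, alt):
        return MESite(precursor_id="p", position=40, ref=ref, alt=alt,
                      support=10, depth=20, mature_position=pos)

    def test_simple_substitution(self):
        out = apply_edit("UAGGUAGUAGGUUGUAUAGUU", self._site(2, "A", "G"))
        assert out == "UGGGUAGUAGGUUGUAUAGUU"

    def test_a_to_i_reads_as_g(self):
        out = apply_edit("UAGGUAGUAGGUUGUAUAGUU", self._site(6, "A", "G"))
        assert out[5] == "G"

    def test_reapplying_edit_is_reference_mismatch(self):
        site = self._site(2, "A", "G")
        once = apply_edit("UAGGUAGUAGGUUGUAUAGUU", site)
        with pytest.raises(ValueError):
            apply_edit(once, site)

    def test_null_position_rejected(self):
        site = MESite(precursor_id="p", position=40, ref="A", alt="G",
                      support=10, depth=20, mature_position=None)
        with pytest.raises(ValueError):
            apply_edit("UAGGUAGUAGGUUGUAUAGUU", site)

    def test_dna_alphabet_preserved(self):
        out = apply_edit("TAGGTAGTAGGTTGTATAGTT", self._site(2, "A", "G"))
        assert out == "TGGGTAGTAGGTTGTATAGTT"


def _revcomp(s):
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


class TestPredictTargets:
    MIRNA = "TCGAATCGGATCGTACGGTTAA"  # seed (1-8) TCGAATCG

    def test_exact_seed_complement_is_target(self):
        site = _revcomp(self.MIRNA[:8])
        utrs = {"t1": "AC" * 10 + site + "CA" * 10}
        hits = predict_targets("m", self.MIRNA, utrs)
        assert {h.transcript_id for h in hits} == {"t1"}
        assert max(h.match_run for h in hits) == 8

    def test_six_match_run_is_not_a_target(self):
        site = list(_revcomp(self.MIRNA[:8]))
        site[3] = "A" if site[3] != "A" else "C"  # break the run centrally
        utrs = {"t1": "AC" * 10 + "".join(site) + "CA" * 10}
        assert predict_targets("m", self.MIRNA, utrs) == []

    def test_agrees_with_exhaustive_window_scan(self):
        rng = random.Random(5)
        utrs = {
            f"t{i}": "".join(rng.choice("ACGT") for _ in range(200))
            for i in range(5)
        }
        utrs["planted"] = "TT" + _revcomp(self.MIRNA[:8]) + "GG"
        got = {
            (h.transcript_id, h.utr_position)
            for h in predict_targets("m", self.MIRNA, utrs)
        }
        wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
        expected = set()
        for tid, utr in utrs.items():
            for s in range(len(utr) - 7):
                window = utr[s : s + 8]
                run = best = 0
                for k in range(8):
                    if (self.MIRNA[k], window[7 - k]) in wc:
                        run += 1
                        best = max(best, run)
                    else:
                        run = 0
                if best >= 7:
                    expected.add((tid, s + 1))
        assert got == expected

    def test_gu_wobble_not_counted(self):
        # complement with one G:U at a seed position only
        site = list(_revcomp(self.MIRNA[:8]))
        # miRNA position 4 is A; replace its partner T by G (A:G not WC;
        # use position with G to test G:U): miRNA position 3 is G, partner C
        # at window index 5 -> replace with T to offer G:U
        site[5] = "T"
        utrs = {"t1": "".join(site)}
        assert predict_targets("m", self.MIRNA, utrs) == []


class TestCompareTargetSets:
    def _targets(self, mirna, ids):
        from miredit.quant_targets import TargetSite

        return [TargetSite(mirna, t, 1, 7) for t in ids]

    def test_identical_sets_fully_shared(self):
        a = self._targets("m", ["t1", "t2"])
        cmp = compare_target_sets(a, a)
        assert cmp.percent_shared == 100.0

    def test_disjoint_sets_share_nothing(self):
        cmp = compare_target_sets(
            self._targets("m", ["t1"]), self._targets("m2", ["t2"])
        )
        assert cmp.percent_shared == 0.0 and cmp.intersection == 0

    def test_symmetry(self):
        a = self._targets("m", ["t1", "t2", "t3"])
        b = self._targets("m2", ["t2", "t4"])
        ab, ba = compare_target_sets(a, b), compare_target_sets(b, a)
        assert ab.percent_shared == ba.percent_shared
        assert (ab.size_a, ab.size_b) == (ba.size_b, ba.size_a)


class TestEnrichSets:
    def test_matches_closed_form_hypergeometric(self):
        universe = [f"g{i}" for i in range(100)]
        term_genes = universe[:10]
        targets = universe[:5]
        df = enrich_sets(targets, {"T": term_genes}, universe)
        expected = float(stats.hypergeom.sf(4, 100, 10, 5))
        assert df.iloc[0]["p_value"] == pytest.approx(expected, rel=1e-12)
        assert bool(df.iloc[0]["significant"])

    def test_targets_equal_universe_never_enriched(self):
        universe = [f"g{i}" for i in range(50)]
        df = enrich_sets(universe, {"T": universe[:20]}, universe)
        assert df.iloc[0]["p_value"] == pytest.approx(1.0)
        assert not bool(df.iloc[0]["significant"])

    def test_empty_targets_no_rows_significant(self):
        universe = [f"g{i}" for i in range(10)]
        df = enrich_sets([], {"T": universe[:5]}, universe)
        assert not df["significant"].any()

    def test_empty_term_skipped(self):
        universe = ["g1", "g2"]
        df = enrich_sets(["g1"], {"T": []}, universe)
        assert df.empty
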