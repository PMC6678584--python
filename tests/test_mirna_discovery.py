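"""Homology mapping, candidate folding, de-novo filter chain, merging."""

import random

import pytest

from miredit.mirna_discovery import (
    DiscoveryConfig,
    Precursor,
    build_homology_candidates,
    discover_species_specific,
    load_precursor_annotation,
    map_known_matures,
    merge_annotations,
    read_accumulation_check,
    write_precursor_annotation,
)
from miredit.read_alignment import PrecursorAlignment
from miredit.sequence_io import GenomicLocus, SmallRead, reverse_complement
from miredit.synthetic_data import (
    SimulationConfig,
    build_discovery_study,
    build_genome,
)


def _mutate(seq, positions):
    out = list(seq)
    for i in positions:
        out[i] = "A" if out[i] != "A" else "G"
    return "".join(out)


@pytest.fixture(scope="module")
def planted_genome():
    cfg = SimulationConfig(n_precursors=2, seed=13, genome_length=2000)
    return build_genome(cfg)


class TestMapKnownMatures:
    def test_exact_copy_single_hit(self, planted_genome):
        genome, truth = planted_genome
        prec = truth.precursors[0]
        mature = prec.sequence[prec.mature5p[0] - 1 : prec.mature5p[1]]
        hits = map_known_matures({"m": mature}, genome)
        exact = [h for h in hits if h.mismatches == 0]
        assert len(exact) == 1
        assert exact[0].locus.strand == prec.locus.strand

    def test_mismatch_budget_two(self, planted_genome):
        genome, truth = planted_genome
        prec = truth.precursors[0]
        mature = prec.sequence[prec.mature5p[0] - 1 : prec.mature5p[1]]
        two = _mutate(mature, [4, 12])
        three = _mutate(mature, [4, 12, 18])
        assert map_known_matures({"m": two}, genome)
        assert map_known_matures({"m": three}, genome) == []

    def test_reverse_complement_found_on_minus_strand(self, planted_genome):
        genome, truth = planted_genome
        prec = truth.precursors[0]
        mature = prec.sequence[prec.mature5p[0] - 1 : prec.mature5p[1]]
        hits = map_known_matures({"m": reverse_complement(mature)}, genome)
        strands = {h.locus.strand for h in hits if h.mismatches == 0}
        assert strands == {"+" if prec.locus.strand == "-" else "-"}

    def test_duplicate_matures_collapsed(self, planted_genome):
        genome, truth = planted_genome
        prec = truth.precursors[0]
        mature = prec.sequence[prec.mature5p[0] - 1 : prec.mature5p[1]]
        hits = map_known_matures({"a": mature, "b": mature}, genome)
        assert len([h for h in hits if h.mismatches == 0]) == 1


class TestBuildHomologyCandidates:
    def test_planted_precursor_survives(self, planted_genome):
        genome, truth = planted_genome
        prec = truth.precursors[0]
        mature = prec.sequence[prec.mature5p[0] - 1 : prec.mature5p[1]]
        hits = map_known_matures({"m": mature}, genome)
        cands = build_homology_candidates(
            [h for h in hits if h.mismatches == 0], genome
        )
        assert len(cands) == 1
        assert cands[0].matures  # mature attached to one arm
        assert cands[0].source == "homology"

    def test_mature_in_unstructured_background_rejected(self):
        rng = random.Random(3)
        background = "".join(rng.choice("AC") for _ in range(400))
        mature = "".join(rng.choice("AC") for _ in range(22))
        genome = {"c": background[:200] + mature + background[200:]}
        hits = map_known_matures({"m": mature}, genome)
        exact = [h for h in hits if h.mismatches == 0]
        assert build_homology_candidates(exact, genome) == []

    def test_truncated_window_flagged(self, planted_genome):
        genome, truth = planted_genome
        prec = truth.precursors[0]
        # a hit 10 nt from the chromosome start forces window truncation
        mature = genome[prec.locus.chrom][10:32]
        from miredit.mirna_discovery import MatureHit

        hit = MatureHit("m", mature,
                        GenomicLocus(prec.locus.chrom, 11, 32, "+", "m"), 0)
        cands = build_homology_candidates([hit], genome)
        if cands:  # background window rarely folds; the flag is the contract
            assert "truncated" in cands[0].flags


class TestReadAccumulation:
    def _prec(self):
        return Precursor(
            id="p", sequence="A" * 100, matures={"5p": (10, 31)}
        )

    def _alns(self, inside, outside):
        out = []
        if inside:
            out.append(PrecursorAlignment(
                SmallRead("A" * 22, inside), "p", 9, ()))
        if outside:
            out.append(PrecursorAlignment(
                SmallRead("A" * 22, outside), "p", 60, ()))
        return out

    def test_70_percent_passes(self):
        frac, ok = read_accumulation_check(self._prec(), self._alns(70, 30))
        assert frac == pytest.approx(0.70) and ok

    def test_64_percent_fails(self):
        frac, ok = read_accumulation_check(self._prec(), self._alns(64, 36))
        assert frac == pytest.approx(0.64) and not ok

    def test_no_reads_fails_with_zero(self):
        frac, ok = read_accumulation_check(self._prec(), [])
        assert frac == 0.0 and not ok

    def test_all_reads_in_loop_fail(self):
        frac, ok = read_accumulation_check(self._prec(), self._alns(0, 50))
        assert frac == 0.0 and not ok


@pytest.fixture(scope="module")
def result():
    study = build_discovery_study(seed=0)
    res = discover_species_specific(
        [study.profile], study.genome, {}, DiscoveryConfig()
    )
    return study, res


class TestDiscoverSpeciesSpecific:
    def test_planted_novel_precursor_recovered(self, result):
        study, res = result
        assert study.expected_id in [p.id for p in res.precursors]

    def test_each_decoy_rejected_with_clause_named(self, result):
        study, res = result
        for cid, clause in study.decoy_clauses.items():
            assert clause in res.rejections.get(cid, []), (cid, clause)

    def test_single_clause_decoys_name_only_that_clause(self, result):
        study, res = result
        for cid, clause in study.decoy_clauses.items():
            if clause == "min_paired":
                continue  # short stems cannot reach the energy gate either
            assert res.rejections[cid] == [clause]

    def test_filter_chain_is_monotone(self, result):
        _study, res = result
        numeric = [n for _step, n in res.attrition[1:]]
        assert all(a >= b for a, b in zip(numeric, numeric[1:]))

    def test_blocklisted_sequences_removed(self):
        study = build_discovery_study(seed=0)
        good_arm = None
        for rec in study.profile:
            if rec.id.startswith("good-m5"):
                good_arm = rec.sequence[:22]
                break
        blocklists = {"rRNA": {"block1": good_arm}}
        res = discover_species_specific(
            [study.profile], study.genome, blocklists, DiscoveryConfig()
        )
        assert study.expected_id not in [p.id for p in res.precursors]

    def test_missing_blocklist_skipped_with_warning(self, caplog):
        study = build_discovery_study(seed=0)
        import logging

        with caplog.at_level(logging.WARNING):
            res = discover_species_specific(
                [study.profile], study.genome, {"repeats": None},
                DiscoveryConfig(),
            )
        assert "repeats" in caplog.text
        assert study.expected_id in [p.id for p in res.precursors]


class TestMergeAnnotations:
    def _prec(self, pid, start, end, strand="+", matures=None):
        seq = "ACGT" * ((end - start + 1) // 4 + 20)
        seq = seq[: max(end - start + 1, 60)]
        return Precursor(
            id=pid, sequence=seq,
            locus=GenomicLocus("c", start, end, strand, id=pid),
            matures=matures or {},
        )

    def test_overlapping_entries_unified_with_provenance(self):
        a = self._prec("d1", 100, 180)
        b = self._prec("m1", 120, 200)
        merged = merge_annotations([a], [b], [])
        assert len(merged) == 1
        assert {"src:discovered", "src:mirbase"} <= set(merged[0].flags)

    def test_disjoint_inputs_concatenate(self):
        a = self._prec("d1", 100, 180)
        b = self._prec("m1", 400, 480)
        c = self._prec("e1", 800, 880)
        assert len(merge_annotations([a], [b], [c])) == 3

    def test_order_independent(self):
        a = self._prec("d1", 100, 180)
        b = self._prec("m1", 120, 200)
        c = self._prec("e1", 800, 880)
        def ids(ms):
            return sorted(p.id for p in ms)

        m1 = merge_annotations([a], [b], [c])
        m2 = merge_annotations([c], [a], [b])
        m3 = merge_annotations([b, c, a], [], [])
        assert ids(m1) == ids(m2) == ids(m3)

    def test_known_mature_attached_to_import_only_precursor(self):
        cfg = SimulationConfig(n_precursors=1, seed=19, genome_length=1000)
        _genome, truth = build_genome(cfg)
        planted = truth.precursors[0]
        bare = Precursor(id="ens1", sequence=planted.sequence,
                         locus=planted.locus)
        mature = planted.sequence[
            planted.mature5p[0] - 1 : planted.mature5p[1]
        ]
        merged = merge_annotations([], [], [bare], known_matures={"m": mature})
        assert merged[0].matures
        assert "matures_attached" in merged[0].flags

    def test_strand_conflict_kept_separate(self):
        a = self._prec("d1", 100, 180, "+")
        b = self._prec("m1", 100, 180, "-")
        assert len(merge_annotations([a], [b], [])) == 2


class TestAnnotationRoundTrip:
    def test_write_then_load(self, tmp_path, planted_genome):
        _genome, truth = planted_genome
        from miredit.pipeline import precursors_from_truth

        precs = precursors_from_truth(truth)
        gff = tmp_path / "loci.gff3"
        write_precursor_annotation(precs.values(), gff)
        loaded = load_precursor_annotation(
            {p.id: p.sequence for p in precs.values()}, gff
        )
        assert set(loaded) == set(precs)
        for pid in precs:
            assert loaded[pid].matures == dict(precs[pid].matures)
            assert loaded[pid].locus == precs[pid].locus
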