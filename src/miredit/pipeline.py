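"""End-to-end editing-site analysis over one or more sequencing profiles.

Chains the module layers in the canonical order: quality gate → adapter trim
→ collapse → alignment to precursors (with 3'-tail splitting) → genome
alignment → cross-mapping correction → weighted variant tallies → binomial
significance with BH correction → category classification → SNP relabeling →
sample combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .editing_sites import (
    EditingConfig,
    MESite,
    SNPRecord,
    adjust_and_filter,
    call_snps,
    classify_site,
    combine_samples,
    CombinedSites,
    sites_from_tallies,
    tally_variants,
)
from .mirna_discovery import Precursor
from .read_alignment import (
    align_to_genome,
    align_to_precursors,
    cross_map_correct,
    locus_key,
)
from .sequence_io import FastqRecord, preprocess_profile
from .synthetic_data import TruthManifest


def precursors_from_truth(truth: TruthManifest) -> dict[str, Precursor]:
    """Lift the simulator's planted loci into analysis-ready precursors
    (decoys excluded)."""
    out = {}
    for p in truth.precursors:
        if p.is_decoy:
            continue
        out[p.id] = Precursor(
            id=p.id,
            sequence=p.sequence,
            locus=p.locus,
            matures={"5p": p.mature5p, "3p": p.mature3p},
            source="imported",
        )
    return out


def snp_records_from_truth(truth: TruthManifest) -> list[SNPRecord]:
    return [
        SNPRecord(chrom=c, position=p, ref=r, alt=a, rsid=rs)
        for c, p, r, a, rs in truth.snp_table
    ]


@dataclass
class SampleResult:
    sample_id: str
    candidate_sites: list[MESite]
    significant_sites: list[MESite]
    mature_counts: dict[str, float] = field(default_factory=dict)


def _hit_in_precursor(hit, precursor: Precursor) -> bool:
    loc = precursor.locus
    return (
        loc is not None
        and hit.chrom == loc.chrom
        and hit.strand == loc.strand
        and loc.start <= hit.start <= loc.end
    )


def analyze_sample(
    records: Iterable[FastqRecord],
    precursors: Mapping[str, Precursor],
    genome: Mapping[str, str],
    sample_id: str = "sample",
    cfg: EditingConfig | None = None,
) -> SampleResult:
    """Identify and classify M/E sites in one profile.

    Cross-mapping correction: reads mapping to several genomic loci are
    weighted per locus by the loci's mismatch-free read support; a
    precursor's tally uses the weight mass falling inside its own locus, and
    a site whose supporting reads carry >= 50% weight elsewhere is
    classified Pseudo.
    """
    cfg = cfg or EditingConfig()
    reads = preprocess_profile(records, q_min=cfg.q_threshold)
    prec_seqs = {p.id: p.sequence for p in precursors.values()}
    alignments = align_to_precursors(reads, prec_seqs)
    mapped_seqs = {a.read.sequence for a in alignments}
    mapped_reads = [r for r in reads if r.sequence in mapped_seqs]

    genome_hits = align_to_genome(mapped_reads, genome, max_mismatches=1)
    perfect: dict[str, float] = {}
    for r in mapped_reads:
        for h in genome_hits.get(r.sequence, ()):
            if h.mismatches == 0:
                key = locus_key(h)
                perfect[key] = perfect.get(key, 0.0) + r.count
    multi = {
        r.sequence: [locus_key(h) for h in genome_hits.get(r.sequence, ())]
        for r in mapped_reads
        if genome_hits.get(r.sequence)
    }
    weights = {w.sequence: w.weights for w in cross_map_correct(multi, perfect)}

    hit_by_key = {
        locus_key(h): h
        for hits in genome_hits.values()
        for h in hits
    }

    candidate_sites: list[MESite] = []
    elsewhere_by_site: dict[tuple[str, int, str, bool], float] = {}
    for pid, prec in sorted(precursors.items()):
        w_prec: dict[str, float] = {}
        w_else: dict[str, float] = {}
        for seq, per_locus in weights.items():
            inside = sum(
                w for key, w in per_locus.items()
                if _hit_in_precursor(hit_by_key[key], prec)
            )
            w_prec[seq] = inside
            w_else[seq] = 1.0 - inside
        # reads with no genomic hit at all keep weight 1 on the precursor
        for r in mapped_reads:
            if r.sequence not in w_prec:
                w_prec[r.sequence] = 1.0
                w_else[r.sequence] = 0.0
        prec_alns = [a for a in alignments if a.precursor_id == pid]
        tallies = tally_variants(prec_alns, prec, weights=w_prec)
        sites = sites_from_tallies(tallies, prec, sample_id=sample_id, cfg=cfg)
        # per-site count-weighted mean of the supporting reads' weight mass
        # on other loci (drives the Pseudo classification)
        else_mass: dict[tuple[int, str, bool], float] = {}
        supp_count: dict[tuple[int, str, bool], float] = {}
        for a in prec_alns:
            c = a.read.count
            we = w_else.get(a.read.sequence, 0.0)
            keys = [(pos, alt, False) for pos, _ref, alt in a.mismatches]
            keys += [
                (a.templated_end + 1 + i, nt, True)
                for i, nt in enumerate(a.soft_tail)
            ]
            for k in keys:
                else_mass[k] = else_mass.get(k, 0.0) + c * we
                supp_count[k] = supp_count.get(k, 0.0) + c
        for k, total in supp_count.items():
            if total > 0:
                elsewhere_by_site[(pid,) + k] = else_mass[k] / total
        candidate_sites.extend(sites)

    significant = adjust_and_filter(candidate_sites, cfg)
    classified = [
        classify_site(
            s,
            precursors[s.precursor_id],
            cross_weight_elsewhere=elsewhere_by_site.get(
                (s.precursor_id, s.position, s.alt, s.is_tail), 0.0
            ),
            cfg=cfg,
        )
        for s in significant
    ]

    mature_counts: dict[str, float] = {}
    for a in alignments:
        prec = precursors[a.precursor_id]
        for arm, (s, e) in prec.matures.items():
            if a.offset >= s - 2 and a.templated_end <= e + 2:
                mid = f"{a.precursor_id}-{arm}"
                mature_counts[mid] = mature_counts.get(mid, 0.0) + a.read.count
                break
    return SampleResult(
        sample_id=sample_id,
        candidate_sites=candidate_sites,
        significant_sites=classified,
        mature_counts=mature_counts,
    )


@dataclass
class StudyResult:
    samples: list[SampleResult]
    sites: list[MESite]  # significant, classified, SNP-relabeled
    combined: CombinedSites


def run_study(
    profiles: Sequence[tuple[str, Iterable[FastqRecord]]],
    precursors: Mapping[str, Precursor],
    genome: Mapping[str, str],
    snp_table: Sequence[SNPRecord] = (),
    sample_tissue: Mapping[str, str] | None = None,
    cfg: EditingConfig | None = None,
) -> StudyResult:
    """Analyze several profiles and combine per-sample results.

    SNP relabeling runs after combination so that the 100%-level clause sees
    the maximum level across all samples.
    """
    cfg = cfg or EditingConfig()
    results = [
        analyze_sample(records, precursors, genome, sample_id=sid, cfg=cfg)
        for sid, records in profiles
    ]
    all_sites = [s for r in results for s in r.significant_sites]
    all_sites = call_snps(all_sites, snp_table, dict(precursors))
    significant_ids = {
        r.sample_id: {s.site_id for s in r.significant_sites} for r in results
    }
    combined = combine_samples(
        [(r.sample_id, [s for s in all_sites if s.sample_id == r.sample_id])
         for r in results],
        sample_tissue=sample_tissue,
        significant_ids=significant_ids,
    )
    return StudyResult(samples=results, sites=all_sites, combined=combined)
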