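"""Conserved-miRNA homology discovery and species-specific precursor
discovery from small-RNA profiles.

Two entry points:

* :func:`map_known_matures` + :func:`build_homology_candidates` — the
  homology route: known animal mature miRNAs are scanned against the genome
  (end-to-end, up to two mismatches, both strands), flanks of ±80 nt are
  folded, and candidates are kept when the mature sits cleanly on one arm of
  a hairpin.
* :func:`discover_species_specific` — the stringent de-novo route: an
  ordered filter chain over the profiles (quality gate, trim/collapse,
  genome mappability, blocklist subtraction, abundance, hairpin folding
  gates, read-accumulation and duplex-overhang checks) with per-step
  attrition counts and named rejection reasons for failed candidates.

The filter chain is monotone: each step only removes survivors of the
previous step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .hairpin_fold import (
    HairpinCriteria,
    HairpinStructure,
    MatureCriteria,
    check_duplex_overhang,
    check_hairpin_criteria,
    evaluate_mature_placement,
    fold_hairpin,
)
from .read_alignment import (
    PrecursorAlignment,
    _KmerIndex,
    align_to_genome,
    align_to_precursors,
)
from .sequence_io import (
    FastqRecord,
    GenomicLocus,
    SmallRead,
    intersect_loci,
    preprocess_profile,
    reverse_complement,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Precursor:
    """A pre-miRNA with sequence, genomic locus, fold and mature spans."""

    id: str
    sequence: str
    locus: GenomicLocus | None = None
    structure: HairpinStructure | None = None
    matures: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    source: str = "imported"  # homology | novel | imported
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for arm, (s, e) in self.matures.items():
            if arm not in {"5p", "3p"}:
                raise ValueError(f"bad arm {arm!r}")
            if not (1 <= s <= e <= len(self.sequence)):
                raise ValueError(f"mature span {s}-{e} outside precursor")

    @property
    def has_matures(self) -> bool:
        return bool(self.matures)


@dataclass(frozen=True)
class DiscoveryConfig:
    max_homology_mismatches: int = 2
    flank_nt: int = 80
    min_total_reads: int = 10
    accumulation_fraction: float = 0.65
    shift_nt: int = 2
    hairpin: HairpinCriteria = HairpinCriteria()
    mature: MatureCriteria = MatureCriteria()
    overhang_tolerance: int = 1


@dataclass(frozen=True)
class MatureHit:
    mature_id: str
    sequence: str
    locus: GenomicLocus
    mismatches: int


# ---------------------------------------------------------------------------
# homology route
# ---------------------------------------------------------------------------

def _scan_with_mismatches(
    query: str, genome: Mapping[str, str], index: _KmerIndex, max_mm: int
) -> list[tuple[str, int, str, int]]:
    """(chrom, 0-based start, strand, mismatches) for end-to-end hits."""
    k = index.k
    hits = []
    seen = set()
    for strand in "+-":
        q = query if strand == "+" else reverse_complement(query)
        offsets = [i * k for i in range(max_mm + 1) if (i + 1) * k <= len(q)]
        if not offsets:
            offsets = [0]
        for chrom, start0 in index.candidates(q, offsets):
            if (chrom, start0, strand) in seen:
                continue
            seen.add((chrom, start0, strand))
            ref = genome[chrom]
            if start0 + len(q) > len(ref):
                continue
            mm = sum(
                1 for a, b in zip(q, ref[start0 : start0 + len(q)]) if a != b
            )
            if mm <= max_mm:
                hits.append((chrom, start0, strand, mm))
    return hits


def map_known_matures(
    matures: Mapping[str, str],
    genome: Mapping[str, str],
    cfg: DiscoveryConfig | None = None,
) -> list[MatureHit]:
    """Map known mature miRNAs to the genome, both strands, no indels.

    Duplicate mature sequences are collapsed first (one representative id,
    lexicographically smallest). Hits with more than
    ``cfg.max_homology_mismatches`` mismatches are discarded.
    """
    cfg = cfg or DiscoveryConfig()
    unique: dict[str, str] = {}
    for mid in sorted(matures):
        seq = matures[mid].upper().replace("U", "T")
        unique.setdefault(seq, mid)
    if not unique:
        return []
    k = max(4, min(len(s) for s in unique) // (cfg.max_homology_mismatches + 1))
    index = _KmerIndex(genome, k)
    out = []
    for seq, mid in sorted(unique.items(), key=lambda kv: kv[1]):
        for chrom, s0, strand, mm in _scan_with_mismatches(
            seq, genome, index, cfg.max_homology_mismatches
        ):
            out.append(
                MatureHit(
                    mature_id=mid,
                    sequence=seq,
                    locus=GenomicLocus(
                        chrom, s0 + 1, s0 + len(seq), strand, id=mid
                    ),
                    mismatches=mm,
                )
            )
    out.sort(key=lambda h: (h.locus.chrom, h.locus.start, h.locus.strand, h.mature_id))
    return out


def _mature_on_one_arm(
    structure: HairpinStructure, span: tuple[int, int]
) -> str | None:
    """'5p'/'3p' when all paired bases of the span pair outside it on one
    side; None when the span straddles the loop or is unpaired."""
    partner = structure.partner_map()
    sides = set()
    for p in range(span[0] - 1, span[1]):
        j = partner.get(p)
        if j is None:
            continue
        if span[0] - 1 <= j <= span[1] - 1:
            return None  # pairs within itself: spans the terminal loop
        sides.add("5p" if j > p else "3p")
    if len(sides) != 1:
        return None
    return sides.pop()


def build_homology_candidates(
    hits: Sequence[MatureHit],
    genome: Mapping[str, str],
    cfg: DiscoveryConfig | None = None,
) -> list[Precursor]:
    """Fold ±``flank_nt`` windows around mature hits into precursor
    candidates; keep those where the mature lies on one hairpin arm and the
    placement criteria pass. Windows truncated at a chromosome edge are
    evaluated and flagged ``truncated``."""
    cfg = cfg or DiscoveryConfig()
    out = []
    for n, hit in enumerate(hits):
        chrom_seq = genome[hit.locus.chrom]
        w_start = hit.locus.start - cfg.flank_nt
        w_end = hit.locus.end + cfg.flank_nt
        flags = []
        if w_start < 1 or w_end > len(chrom_seq):
            flags.append("truncated")
            w_start = max(1, w_start)
            w_end = min(len(chrom_seq), w_end)
        window = chrom_seq[w_start - 1 : w_end]
        if hit.locus.strand == "+":
            mat = (hit.locus.start - w_start + 1, hit.locus.end - w_start + 1)
        else:
            window = reverse_complement(window)
            mat = (w_end - hit.locus.end + 1, w_end - hit.locus.start + 1)
        structure = fold_hairpin(window)
        arm = _mature_on_one_arm(structure, mat)
        if arm is None:
            continue
        ok, _stats = evaluate_mature_placement(structure, mat, cfg.mature)
        if not ok:
            continue
        out.append(
            Precursor(
                id=f"cand-{hit.mature_id}-{n}",
                sequence=window,
                locus=GenomicLocus(
                    hit.locus.chrom, w_start, w_end, hit.locus.strand,
                    id=f"cand-{hit.mature_id}-{n}",
                ),
                structure=structure,
                matures={arm: mat},
                source="homology",
                flags=tuple(flags),
            )
        )
    return out


# ---------------------------------------------------------------------------
# read accumulation
# ---------------------------------------------------------------------------

def read_accumulation_check(
    precursor: Precursor,
    alignments: Sequence[PrecursorAlignment],
    cfg: DiscoveryConfig | None = None,
) -> tuple[float, bool]:
    """Fraction of aligned read counts whose templated span lies within a
    mature span extended by ±``shift_nt``; passes at
    ``accumulation_fraction`` (default 65%). Zero aligned reads fail with
    fraction 0."""
    cfg = cfg or DiscoveryConfig()
    total = 0
    inside = 0
    for a in alignments:
        if a.precursor_id != precursor.id:
            continue
        total += a.read.count
        for s, e in precursor.matures.values():
            if (
                a.offset >= s - cfg.shift_nt
                and a.templated_end <= e + cfg.shift_nt
            ):
                inside += a.read.count
                break
    if total == 0:
        return 0.0, False
    frac = inside / total
    return frac, frac >= cfg.accumulation_fraction


# ---------------------------------------------------------------------------
# species-specific (de novo) route
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryResult:
    precursors: list[Precursor]
    attrition: list[tuple[str, int]]  # (step description, surviving items)
    rejections: dict[str, list[str]]  # candidate id -> violated clauses

    def write_attrition_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("step\tsurvivors\n")
            for step, n in self.attrition:
                fh.write(f"{step}\t{n}\n")


def _blocklist_filter(
    sequences: dict[str, int],
    blocklist: Mapping[str, str],
    max_mm: int,
) -> dict[str, int]:
    if not sequences:
        return {}
    reads = [SmallRead(s, c) for s, c in sequences.items()]
    hits = align_to_genome(reads, dict(blocklist), max_mismatches=max_mm)
    return {s: c for s, c in sequences.items() if not hits.get(s)}


def discover_species_specific(
    profiles: Sequence[Sequence[FastqRecord]],
    genome: Mapping[str, str],
    blocklists: Mapping[str, Mapping[str, str] | None],
    cfg: DiscoveryConfig | None = None,
) -> DiscoveryResult:
    """Run the ordered de-novo discovery filter chain.

    ``blocklists`` maps category name (e.g. ``mRNA``, ``pre_miRNA``,
    ``ncRNA``, ``repeat``) to FASTA-like mappings; a missing (None) list is
    skipped with a warning. Returns survivors plus per-step attrition and,
    for every folded candidate locus that was rejected, the named violated
    clauses (``energy``, ``min_paired``, ``loop_count``, ``accumulation``,
    ``overhang``, ``min_total_reads``).
    """
    cfg = cfg or DiscoveryConfig()
    attrition: list[tuple[str, int]] = []
    rejections: dict[str, list[str]] = {}

    # steps 1-2: gate, trim, collapse; sum counts across profiles
    n_raw = sum(len(p) for p in profiles)
    attrition.append(("raw_reads", n_raw))
    counts: dict[str, int] = {}
    for prof in profiles:
        for sr in preprocess_profile(prof):
            counts[sr.sequence] = counts.get(sr.sequence, 0) + sr.count
    attrition.append(("gated_trimmed_unique", len(counts)))

    # step 3: genome-mappable (either strand)
    reads = [SmallRead(s, c) for s, c in counts.items()]
    genome_hits = align_to_genome(
        reads, genome, max_mismatches=cfg.max_homology_mismatches
    )
    counts = {s: c for s, c in counts.items() if genome_hits.get(s)}
    attrition.append(("genome_mappable", len(counts)))

    # steps 4-7: blocklist subtraction
    for name in sorted(blocklists):
        bl = blocklists[name]
        if bl is None:
            logger.warning("blocklist %r missing; filter skipped", name)
            continue
        counts = _blocklist_filter(counts, bl, cfg.max_homology_mismatches)
        attrition.append((f"not_{name}", len(counts)))

    # step 8: abundance across profiles
    dropped_low = {s: c for s, c in counts.items() if c < cfg.min_total_reads}
    counts = {s: c for s, c in counts.items() if c >= cfg.min_total_reads}
    attrition.append(("min_total_reads", len(counts)))

    def merged_windows(seqs: Iterable[str]) -> list[tuple[str, int, int, str]]:
        """±flank windows around each sequence's best hits, merged per
        chrom/strand."""
        windows: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for s in seqs:
            hits = genome_hits[s]
            best_mm = min(h.mismatches for h in hits)
            for h in hits:
                if h.mismatches != best_mm:
                    continue
                ws = max(1, h.start - cfg.flank_nt)
                we = min(
                    len(genome[h.chrom]), h.start + len(s) - 1 + cfg.flank_nt
                )
                windows.setdefault((h.chrom, h.strand), []).append((ws, we))
        out: list[tuple[str, int, int, str]] = []
        for (chrom, strand), spans in sorted(windows.items()):
            spans.sort()
            cur_s, cur_e = spans[0]
            for s0, e0 in spans[1:]:
                if s0 <= cur_e:
                    cur_e = max(cur_e, e0)
                else:
                    out.append((chrom, cur_s, cur_e, strand))
                    cur_s, cur_e = s0, e0
            out.append((chrom, cur_s, cur_e, strand))
        return out

    # step 9: candidate loci from surviving reads; loci supported only by
    # low-abundance reads are recorded as rejected on that clause
    candidates = merged_windows(counts)
    survivor_spans = {
        (chrom, strand): [(s0, e0) for c2, s0, e0, st2 in candidates
                          if (c2, st2) == (chrom, strand)]
        for chrom, _s0, _e0, strand in candidates
    }
    for chrom, ws, we, strand in merged_windows(dropped_low):
        overlaps = any(
            s0 <= we and ws <= e0
            for s0, e0 in survivor_spans.get((chrom, strand), ())
        )
        if not overlaps:
            rejections[f"novel-{chrom}-{ws}-{strand}"] = ["min_total_reads"]
    attrition.append(("candidate_loci", len(candidates)))

    # steps 10-12: fold, hairpin gates, accumulation + overhang
    surviving_reads = [SmallRead(s, c) for s, c in counts.items()]
    survivors: list[Precursor] = []
    for chrom, ws, we, strand in candidates:
        seq = genome[chrom][ws - 1 : we]
        if strand == "-":
            seq = reverse_complement(seq)
        cid = f"novel-{chrom}-{ws}-{strand}"
        structure = fold_hairpin(seq)
        ok, reasons = check_hairpin_criteria(structure, cfg.hairpin)
        if not ok:
            rejections[cid] = reasons
            continue
        cand = Precursor(
            id=cid,
            sequence=seq,
            locus=GenomicLocus(chrom, ws, we, strand, id=cid),
            structure=structure,
            source="novel",
        )
        aligned = align_to_precursors(surviving_reads, {cid: seq})
        matures = _infer_matures(structure, aligned)
        cand = replace(cand, matures=matures)
        frac, acc_ok = read_accumulation_check(cand, aligned, cfg)
        reasons = []
        if not acc_ok:
            reasons.append("accumulation")
        if {"5p", "3p"} <= set(matures):
            ov_ok, _ = check_duplex_overhang(
                structure, matures["5p"], matures["3p"],
                tolerance=cfg.overhang_tolerance,
            )
            if not ov_ok:
                reasons.append("overhang")
        if reasons:
            rejections[cid] = reasons
            continue
        survivors.append(cand)
    attrition.append(("passed_all_filters", len(survivors)))
    return DiscoveryResult(survivors, attrition, rejections)


def _infer_matures(
    structure: HairpinStructure,
    alignments: Sequence[PrecursorAlignment],
) -> dict[str, tuple[int, int]]:
    """Most-abundant read span on each side of the terminal loop."""
    # terminal loop center: midpoint of the innermost pair
    loop_mid = structure.length / 2
    pairs = sorted(structure.pairs)
    if pairs:
        from .hairpin_fold import _children_map

        children = _children_map(pairs)
        leaves = [p for p, kids in children.items() if p is not None and not kids]
        if leaves:
            i, j = leaves[0]
            loop_mid = (i + j) / 2
    best: dict[str, tuple[int, tuple[int, int]]] = {}
    for a in alignments:
        span = (a.offset, a.templated_end)
        arm = "5p" if (span[0] + span[1]) / 2 - 1 < loop_mid else "3p"
        cur = best.get(arm)
        cand = (a.read.count, span)
        if cur is None or cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
            best[arm] = cand
    return {arm: span for arm, (_, span) in best.items()}


# ---------------------------------------------------------------------------
# annotation merging
# ---------------------------------------------------------------------------

def _attach_matures(
    precursor: Precursor, known_matures: Mapping[str, str], max_mm: int = 1
) -> Precursor:
    """Attach mature spans by aligning known matures to the precursor
    (end-to-end, up to ``max_mm`` mismatches, sense strand)."""
    if precursor.matures:
        return precursor
    seq = precursor.sequence
    found: dict[str, tuple[int, int]] = {}
    for mid in sorted(known_matures):
        q = known_matures[mid].upper().replace("U", "T")
        for s0 in range(len(seq) - len(q) + 1):
            mm = sum(1 for a, b in zip(q, seq[s0 : s0 + len(q)]) if a != b)
            if mm <= max_mm:
                span = (s0 + 1, s0 + len(q))
                arm = "5p" if (span[0] + span[1]) / 2 <= len(seq) / 2 else "3p"
                if arm not in found:
                    found[arm] = span
    if not found:
        return precursor
    return replace(precursor, matures=found, flags=precursor.flags + ("matures_attached",))


def merge_annotations(
    discovered: Sequence[Precursor],
    imported_mirbase: Sequence[Precursor],
    imported_ensembl: Sequence[Precursor],
    known_matures: Mapping[str, str] | None = None,
) -> list[Precursor]:
    """Unify precursor sets by strand-aware genomic overlap.

    Overlapping same-strand entries collapse into one record carrying all
    provenances (``flags``); the representative is the entry with mature
    annotation if any, else the lexicographically first id. Entries lacking
    matures are matched against ``known_matures`` when provided. The result
    is independent of input order.
    """
    tagged: list[Precursor] = []
    for src, group in (
        ("discovered", discovered),
        ("mirbase", imported_mirbase),
        ("ensembl", imported_ensembl),
    ):
        for p in group:
            if p.locus is None:
                raise ValueError(f"precursor {p.id} lacks a genomic locus")
            tagged.append(replace(p, flags=p.flags + (f"src:{src}",)))
    tagged.sort(key=lambda p: (p.locus.chrom, p.locus.start, p.locus.end,
                               p.locus.strand, p.id))
    # union-find over overlap pairs
    parent = list(range(len(tagged)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    loci = [p.locus for p in tagged]
    idx_of = {id(l): i for i, l in enumerate(loci)}
    for la, lb, _ov in intersect_loci(loci, loci):
        ra, rb = find(idx_of[id(la)]), find(idx_of[id(lb)])
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    groups: dict[int, list[Precursor]] = {}
    for i, p in enumerate(tagged):
        groups.setdefault(find(i), []).append(p)
    merged: list[Precursor] = []
    for root in sorted(groups):
        members = sorted(groups[root], key=lambda p: (not p.has_matures, p.id))
        rep = members[0]
        provenance = tuple(
            sorted({f for m in members for f in m.flags})
        )
        rep = replace(rep, flags=provenance)
        if not rep.has_matures and known_matures:
            rep = _attach_matures(rep, known_matures)
        merged.append(rep)
    merged.sort(key=lambda p: (p.locus.chrom, p.locus.start, p.id))
    return merged


# ---------------------------------------------------------------------------
# annotation files
# ---------------------------------------------------------------------------

def write_precursor_annotation(
    precursors: Iterable[Precursor], gff_path: str | Path
) -> None:
    """GFF3 with one ``pre_miRNA`` feature per precursor and ``miRNA``
    children for mature arms; mature spans are also carried
    precursor-relative in the ``mature_span`` attribute."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in precursors:
            if p.locus is None:
                continue
            loc = p.locus
            fh.write(
                f"{loc.chrom}\tmiredit\tpre_miRNA\t{loc.start}\t{loc.end}\t.\t"
                f"{loc.strand}\t.\tID={p.id}\n"
            )
            for arm, (s, e) in sorted(p.matures.items()):
                if loc.strand == "+":
                    gs, ge = loc.start + s - 1, loc.start + e - 1
                else:
                    gs, ge = loc.end - e + 1, loc.end - s + 1
                fh.write(
                    f"{loc.chrom}\tmiredit\tmiRNA\t{gs}\t{ge}\t.\t"
                    f"{loc.strand}\t.\tID={p.id}-{arm};Parent={p.id};"
                    f"arm={arm};mature_span={s}-{e}\n"
                )


def load_precursor_annotation(
    fasta: Mapping[str, str], gff_path: str | Path
) -> dict[str, Precursor]:
    """Rebuild precursors from a sequence mapping and the GFF3 written by
    :func:`write_precursor_annotation`."""
    pre: dict[str, dict] = {}
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            if f[2] == "pre_miRNA":
                pid = attrs["ID"]
                pre.setdefault(pid, {"matures": {}})["locus"] = GenomicLocus(
                    f[0], int(f[3]), int(f[4]), f[6], id=pid
                )
            elif f[2] == "miRNA" and "Parent" in attrs and "mature_span" in attrs:
                s, e = attrs["mature_span"].split("-")
                pre.setdefault(attrs["Parent"], {"matures": {}})["matures"][
                    attrs.get("arm", "5p")
                ] = (int(s), int(e))
    out = {}
    for pid, info in pre.items():
        if pid not in fasta:
            raise ValueError(f"precursor {pid} missing from FASTA")
        out[pid] = Precursor(
            id=pid,
            sequence=fasta[pid].upper().replace("U", "T"),
            locus=info.get("locus"),
            matures=info["matures"],
            source="imported",
        )
    return out
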