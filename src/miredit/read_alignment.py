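"""Alignment of collapsed reads to precursors and genome, and cross-mapping
correction of multi-mapped reads.

Alignment is end-to-end, substitution-only (no indels), with a budget of one
internal mismatch, mirroring a ``-v 1``-style short-read mapper. A maximal
non-templated 3' suffix of up to three bases is split off as a ``soft_tail``
before the mismatch budget is applied, so that 3' tailing (non-templated A/U
addition) is represented explicitly rather than consuming mismatches.

Reads that map to several loci are reassigned by cross-mapping correction:
each locus receives weight proportional to its perfectly-mapping
(mismatch-free) read support, falling back to a uniform split when no locus
has perfect support. Weights over a read's loci always sum to one, so
weighted tallies conserve read counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .sequence_io import SmallRead, reverse_complement

MAX_SOFT_TAIL = 3
MAX_INTERNAL_MISMATCHES = 1


@dataclass(frozen=True)
class PrecursorAlignment:
    read: SmallRead
    precursor_id: str
    offset: int  # 1-based start on precursor
    mismatches: tuple[tuple[int, str, str], ...]  # (precursor pos, ref, read)
    soft_tail: str = ""

    @property
    def templated_length(self) -> int:
        return len(self.read.sequence) - len(self.soft_tail)

    @property
    def templated_end(self) -> int:
        """1-based precursor position of the last templated base."""
        return self.offset + self.templated_length - 1


@dataclass(frozen=True)
class GenomeHit:
    chrom: str
    start: int  # 1-based position of the read's first base on + strand
    strand: str
    mismatches: int


@dataclass(frozen=True)
class CrossMapWeight:
    sequence: str
    weights: Mapping[str, float]  # locus key -> weight in [0,1], sums to 1


# ---------------------------------------------------------------------------
# k-mer seeded scanning
# ---------------------------------------------------------------------------

class _KmerIndex:
    """Exact k-mer position index over a set of named sequences."""

    def __init__(self, sequences: Mapping[str, str], k: int):
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in sequences.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((name, i))

    def candidates(self, read: str, seed_offsets: Iterable[int]):
        """Candidate (name, read-start) placements from exact seed hits."""
        out: set[tuple[str, int]] = set()
        for off in seed_offsets:
            for name, pos in self.index.get(read[off : off + self.k], ()):
                if pos - off >= 0:
                    out.add((name, pos - off))
        return out


def _seed_offsets(read_len: int, templated_min: int, k: int) -> list[int]:
    # two non-overlapping seeds inside the guaranteed-templated prefix:
    # with <=1 internal mismatch, at least one seed matches exactly
    return [0, k] if 2 * k <= templated_min else [0]


def _verify_precursor(
    read: str, prec: str, start0: int
) -> tuple[tuple[tuple[int, str, str], ...], str] | None:
    """Check an end-to-end placement at 0-based ``start0``; returns
    (mismatches, soft_tail) or None."""
    L = len(read)
    overhang = max(0, start0 + L - len(prec))
    if overhang > MAX_SOFT_TAIL:
        return None
    tail_len = overhang
    # maximal non-templated suffix: extend while the read base disagrees
    # with the template, up to MAX_SOFT_TAIL total
    while (
        tail_len < MAX_SOFT_TAIL
        and tail_len < L
        and read[L - tail_len - 1] != prec[start0 + L - tail_len - 1]
    ):
        tail_len += 1
    templated = L - tail_len
    if templated < 1:
        return None
    mm = []
    for i in range(templated):
        if read[i] != prec[start0 + i]:
            mm.append((start0 + i + 1, prec[start0 + i], read[i]))
            if len(mm) > MAX_INTERNAL_MISMATCHES:
                return None
    return tuple(mm), read[templated:]


def align_to_precursors(
    reads: Sequence[SmallRead],
    precursors: Mapping[str, str],
    *,
    max_tail: int = MAX_SOFT_TAIL,
) -> list[PrecursorAlignment]:
    """Report every end-to-end placement of each read on each precursor.

    A placement is valid when, after splitting off a maximal non-templated 3'
    suffix of at most ``max_tail`` bases, the templated portion matches with
    at most one mismatch. Output is sorted by (read sequence, precursor id,
    offset) for determinism.
    """
    if not reads:
        return []
    min_len = min(len(r.sequence) for r in reads)
    templated_min = max(1, min_len - max_tail)
    k = max(4, templated_min // 2)
    index = _KmerIndex(precursors, k)
    out: list[PrecursorAlignment] = []
    for read in reads:
        seq = read.sequence
        offsets = _seed_offsets(len(seq), len(seq) - max_tail, k)
        hits = set()
        for name, start0 in index.candidates(seq, offsets):
            res = _verify_precursor(seq, precursors[name], start0)
            if res is not None:
                hits.add((name, start0, res))
        for name, start0, (mm, tail) in sorted(
            hits, key=lambda h: (h[0], h[1])
        ):
            out.append(
                PrecursorAlignment(
                    read=read,
                    precursor_id=name,
                    offset=start0 + 1,
                    mismatches=mm,
                    soft_tail=tail,
                )
            )
    out.sort(key=lambda a: (a.read.sequence, a.precursor_id, a.offset))
    return out


def align_to_genome(
    reads: Sequence[SmallRead],
    genome: Mapping[str, str],
    max_mismatches: int = 1,
) -> dict[str, list[GenomeHit]]:
    """All genomic loci (both strands) matching each read end-to-end with at
    most ``max_mismatches`` substitutions. Keyed by read sequence."""
    if not reads:
        return {}
    min_len = min(len(r.sequence) for r in reads)
    k = max(4, min_len // (max_mismatches + 1))
    index = _KmerIndex(genome, k)
    out: dict[str, list[GenomeHit]] = {}
    for read in reads:
        seq = read.sequence
        hits: set[GenomeHit] = set()
        for strand in "+-":
            query = seq if strand == "+" else reverse_complement(seq)
            n_seeds = max_mismatches + 1
            offsets = [
                i * k for i in range(n_seeds) if (i + 1) * k <= len(query)
            ] or [0]
            for chrom, start0 in index.candidates(query, offsets):
                ref = genome[chrom]
                if start0 + len(query) > len(ref):
                    continue
                mm = sum(
                    1
                    for a, b in zip(query, ref[start0 : start0 + len(query)])
                    if a != b
                )
                if mm <= max_mismatches:
                    hits.add(GenomeHit(chrom, start0 + 1, strand, mm))
        out[seq] = sorted(
            hits, key=lambda h: (h.chrom, h.start, h.strand)
        )
    return out


def locus_key(hit: GenomeHit) -> str:
    return f"{hit.chrom}:{hit.start}:{hit.strand}"


def cross_map_correct(
    multi_hits: Mapping[str, Sequence[str]],
    perfect_counts: Mapping[str, float],
) -> list[CrossMapWeight]:
    """Proportionally reassign multi-mapped reads.

    ``multi_hits`` maps a read sequence to its candidate locus keys;
    ``perfect_counts`` gives the mismatch-free read support of each locus.
    Weight of locus Li is perfect(Li) / Σ perfect(Lj), uniform 1/k when all
    candidates have zero perfect support; single-locus reads get weight 1.
    """
    out = []
    for seq in sorted(multi_hits):
        loci = list(multi_hits[seq])
        if not loci:
            continue
        if len(loci) == 1:
            out.append(CrossMapWeight(seq, {loci[0]: 1.0}))
            continue
        support = [max(0.0, float(perfect_counts.get(l, 0.0))) for l in loci]
        total = sum(support)
        if total <= 0:
            w = [1.0 / len(loci)] * len(loci)
        else:
            w = [s / total for s in support]
        out.append(CrossMapWeight(seq, dict(zip(loci, w))))
    return out


def perfect_read_counts(
    alignments: Iterable[PrecursorAlignment],
) -> dict[str, float]:
    """Per-precursor totals of mismatch-free, untailed read counts — the
    expression estimate the cross-mapping correction divides by."""
    out: dict[str, float] = {}
    for a in alignments:
        if not a.mismatches and not a.soft_tail:
            out[a.precursor_id] = out.get(a.precursor_id, 0.0) + a.read.count
    return out
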