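"""Standard-format I/O and small-RNA read preprocessing.

Implements the preprocessing applied to every sequencing profile before
precursor discovery or editing-site analysis: a per-read quality gate on the
first 25 bases, exact 3' adapter trimming, collapsing of identical sequences
into unique reads with counts, and strand-aware interval intersection of
genomic loci.

Coordinates are 1-based inclusive throughout (GFF3 convention).
FASTQ qualities are Phred+33.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

#: 3' sequencing adapter ligated to small RNA molecules (Illumina TruSeq
#: small RNA kit); trimming looks for prefixes of this string.
DEFAULT_ADAPTER = "TGGAATTCTCGAGTGCCAAGGAACTCC"

DEFAULT_MIN_QUALITY = 30
DEFAULT_MIN_LENGTH = 19  # unique reads must be longer than 18 nt
QUALITY_WINDOW = 25  # leading bases inspected by the quality gate
MIN_ADAPTER_MATCH = 6


@dataclass(frozen=True)
class SmallRead:
    """A collapsed unique read.

    Attributes
    ----------
    sequence:
        Uppercase DNA string (post trimming).
    count:
        Number of raw reads collapsed into this sequence.
    min_quality_first25:
        Minimum Phred score seen in the first 25 bases across the collapsed
        raw reads.
    """

    sequence: str
    count: int
    min_quality_first25: int = 93

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass(frozen=True)
class GenomicLocus:
    """A stranded genomic interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str
    id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be +/-, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FastqRecord:
    """One raw FASTQ record with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...]


def read_fastq(path: str | Path | io.TextIOBase) -> Iterator[FastqRecord]:
    """Stream FASTQ records (Phred+33)."""
    for rec in SeqIO.parse(path, "fastq"):
        yield FastqRecord(
            id=rec.id,
            sequence=str(rec.seq).upper(),
            qualities=tuple(rec.letter_annotations["phred_quality"]),
        )


def read_fasta(path: str | Path | io.TextIOBase) -> dict[str, str]:
    """Load a FASTA file as an ordered mapping id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def quality_gate(record: FastqRecord, q_min: int = DEFAULT_MIN_QUALITY) -> bool:
    """Pass iff every one of the first 25 base qualities is >= ``q_min``.

    Records shorter than 25 bases fail (they cannot demonstrate 25 clean
    leading bases); this is a fail, not an error.
    """
    if len(record.qualities) < QUALITY_WINDOW:
        return False
    return all(q >= q_min for q in record.qualities[:QUALITY_WINDOW])


def trim_adapter(
    sequence: str,
    adapter: str = DEFAULT_ADAPTER,
    min_match: int = MIN_ADAPTER_MATCH,
) -> str:
    """Truncate ``sequence`` at the leftmost adapter occurrence.

    A match is a run of >= ``min_match`` bases identical to a prefix of the
    adapter, extending either through the full adapter or to the end of the
    read (a read-through adapter truncated by the read boundary). Matching is
    exact; the sequence is returned unchanged when no match exists.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = sequence.upper()
    ad = adapter.upper()
    for i in range(len(seq)):
        span = min(len(ad), len(seq) - i)
        if span >= min_match and seq[i : i + span] == ad[:span]:
            return seq[:i]
    return seq


def collapse_unique(
    reads: Iterable[FastqRecord | tuple[str, int] | str],
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[SmallRead]:
    """Collapse trimmed, gated reads into unique sequences with counts.

    Sequences shorter than ``min_length`` (default 19, i.e. more than 18 nt)
    are dropped. Accepts FastqRecords, bare strings, or (sequence, count)
    pairs; counts are summed per distinct sequence. Result is sorted by
    descending count then sequence for deterministic output.
    """
    counts: dict[str, int] = {}
    minq: dict[str, int] = {}
    for item in reads:
        if isinstance(item, FastqRecord):
            seq, n = item.sequence, 1
            q = min(item.qualities[:QUALITY_WINDOW]) if item.qualities else 93
        elif isinstance(item, str):
            seq, n, q = item, 1, 93
        else:
            seq, n = item
            q = 93
        seq = seq.upper()
        if len(seq) < min_length:
            continue
        counts[seq] = counts.get(seq, 0) + n
        minq[seq] = min(minq.get(seq, 93), q)
    out = [
        SmallRead(sequence=s, count=c, min_quality_first25=minq[s])
        for s, c in counts.items()
    ]
    out.sort(key=lambda r: (-r.count, r.sequence))
    return out


def intersect_loci(
    set_a: Sequence[GenomicLocus], set_b: Sequence[GenomicLocus]
) -> list[tuple[GenomicLocus, GenomicLocus, int]]:
    """Report same-strand overlapping pairs with overlap length.

    Equivalent to ``bedtools intersect -wo -s`` on 1-based inclusive
    intervals: a pair is reported when chrom and strand agree and the
    intervals share at least one base. Uses a sort-and-sweep over interval
    starts; output order is (A index, B index).
    """
    by_key: dict[tuple[str, str], list[GenomicLocus]] = {}
    for b in set_b:
        by_key.setdefault((b.chrom, b.strand), []).append(b)
    for key in by_key:
        by_key[key].sort(key=lambda l: l.start)
    out: list[tuple[GenomicLocus, GenomicLocus, int]] = []
    for a in set_a:
        candidates = by_key.get((a.chrom, a.strand), [])
        for b in candidates:
            if b.start > a.end:
                break
            ov = min(a.end, b.end) - max(a.start, b.start) + 1
            if ov >= 1:
                out.append((a, b, ov))
    return out


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(loci: Iterable[GenomicLocus], path: str | Path,
               source: str = "miredit", feature: str = "pre_miRNA") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            fh.write(
                f"{loc.chrom}\t{source}\t{feature}\t{loc.start}\t{loc.end}"
                f"\t.\t{loc.strand}\t.\tID={loc.id}\n"
            )


def read_gff3(path: str | Path) -> list[GenomicLocus]:
    loci = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            loci.append(
                GenomicLocus(
                    chrom=f[0],
                    start=int(f[3]),
                    end=int(f[4]),
                    strand=f[6],
                    id=attrs.get("ID", ""),
                )
            )
    return loci


def preprocess_profile(
    records: Iterable[FastqRecord],
    adapter: str = DEFAULT_ADAPTER,
    q_min: int = DEFAULT_MIN_QUALITY,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[SmallRead]:
    """Gate, trim and collapse one sequencing profile in the standard order."""
    trimmed = []
    for rec in records:
        if not quality_gate(rec, q_min):
            continue
        seq = trim_adapter(rec.sequence, adapter)
        if not seq:
            continue
        trimmed.append(
            FastqRecord(rec.id, seq, rec.qualities[: len(seq)] or rec.qualities[:1])
        )
    return collapse_unique(trimmed, min_length=min_length)
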