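"""Synthetic small-RNA study generator with planted ground truth.

Builds a toy genome carrying hairpin-forming precursor loci on both strands,
then simulates collapsed-size (~18–26 nt) small-RNA sequencing reads from the
mature arms with planted central editing events at specified levels, planted
homozygous SNPs, non-templated 3' tails, Phred-quality-driven sequencing
errors, and the literal 3' sequencing adapter — everything the downstream
analysis has to undo. Every emitted read, site and locus is recorded in a
:class:`TruthManifest` so recovery can be scored exactly.

Planted precursors are perfect stem-loops (5' arm, non-pairing loop,
reverse-complement 3' arm) whose mature duplex carries the canonical 2-nt 3'
overhangs; decoy loci are shuffled sequences that fail the hairpin gates.
All randomness flows from a single integer seed and outputs are
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .hairpin_fold import HairpinCriteria, check_hairpin_criteria, fold_hairpin
from .sequence_io import DEFAULT_ADAPTER, GenomicLocus, reverse_complement

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class EditingEvent:
    """A planted editing site: ``position`` is 1-based within the mature."""

    precursor_index: int
    position: int
    ref: str
    alt: str
    level: float
    arm: str = "5p"

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise ValueError("level must be in [0, 1]")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")


@dataclass(frozen=True)
class SnpEvent:
    """A planted homozygous variant: ``position`` is 1-based on the precursor."""

    precursor_index: int
    position: int
    ref: str
    alt: str


@dataclass(frozen=True)
class TailEvent:
    """Non-templated 3' addition applied to reads of one precursor."""

    precursor_index: int
    tail: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 20_000
    n_precursors: int = 10
    n_decoys: int = 0
    precursor_length: int = 80
    mature_length: int = 22
    coverage_per_mature: int = 500
    editing_events: tuple[EditingEvent, ...] = ()
    snp_events: tuple[SnpEvent, ...] = ()
    tail_events: tuple[TailEvent, ...] = ()
    base_quality: int = 40
    seed: int = 0
    spacing: int = 60
    end_jitter: int = 2
    adapter: str = DEFAULT_ADAPTER
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if not 60 <= self.precursor_length <= 110:
            raise ValueError("precursor_length must be in [60, 110]")
        if not 20 <= self.mature_length <= 24:
            raise ValueError("mature_length must be in [20, 24]")


@dataclass(frozen=True)
class PlantedPrecursor:
    id: str
    sequence: str
    locus: GenomicLocus
    mature5p: tuple[int, int]
    mature3p: tuple[int, int]
    is_decoy: bool = False


@dataclass(frozen=True)
class PlantedSite:
    precursor_id: str
    position: int  # 1-based on precursor
    ref: str
    alt: str
    level: float
    kind: str  # "edit" | "snp"
    arm: str
    mature_position: int | None


@dataclass(frozen=True)
class ReadProvenance:
    read_id: str
    precursor_id: str
    arm: str
    start: int  # 1-based on precursor
    end: int
    edits_applied: tuple[int, ...]  # precursor positions
    tail_applied: str
    n_errors: int
    sequence: str  # insert, pre-adapter


@dataclass(frozen=True)
class SimulatedRead:
    id: str
    sequence: str  # insert + adapter as sequenced
    quality: int


@dataclass
class TruthManifest:
    """Planted ground truth for a simulated study."""

    precursors: list[PlantedPrecursor] = field(default_factory=list)
    sites: list[PlantedSite] = field(default_factory=list)
    tails: list[TailEvent] = field(default_factory=list)
    snp_table: list[tuple[str, int, str, str, str]] = field(default_factory=list)
    reads: list[ReadProvenance] = field(default_factory=list)

    def site_truth(self, precursor_id: str, position: int) -> PlantedSite | None:
        for s in self.sites:
            if s.precursor_id == precursor_id and s.position == position:
                return s
        return None

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# record_type\tfields...\n")
            for p in self.precursors:
                fh.write(
                    f"precursor\t{p.id}\t{p.locus.chrom}\t{p.locus.start}\t"
                    f"{p.locus.end}\t{p.locus.strand}\t{p.mature5p[0]}-{p.mature5p[1]}\t"
                    f"{p.mature3p[0]}-{p.mature3p[1]}\t{int(p.is_decoy)}\n"
                )
            for s in self.sites:
                fh.write(
                    f"site\t{s.precursor_id}\t{s.position}\t{s.ref}\t{s.alt}\t"
                    f"{s.level}\t{s.kind}\t{s.arm}\t{s.mature_position}\n"
                )
            for r in self.reads:
                fh.write(
                    f"read\t{r.read_id}\t{r.precursor_id}\t{r.arm}\t{r.start}\t"
                    f"{r.end}\t{','.join(map(str, r.edits_applied)) or '.'}\t"
                    f"{r.tail_applied or '.'}\t{r.n_errors}\n"
                )


def _mature_spans(length: int, mature_length: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Canonical mature placements giving exact 2-nt 3' overhangs on a
    perfect stem (pairing i with L+1-i)."""
    s5 = 3
    return (s5, s5 + mature_length - 1), (length - mature_length + 1, length)


def _precursor_position(
    length: int, mature_length: int, arm: str, mature_pos: int
) -> int:
    (s5, _), (s3, _) = _mature_spans(length, mature_length)
    if arm == "5p":
        return s5 + mature_pos - 1
    if arm == "3p":
        return s3 + mature_pos - 1
    raise ValueError(f"arm must be 5p/3p, got {arm!r}")


WOBBLE_PERIOD = 7  # stem periodicity of planted G·U pairs


def _build_precursor(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    index: int,
) -> str:
    """One stem-loop with planted ref bases forced into the stem.

    The stem is fully paired but carries a G·U wobble roughly every
    :data:`WOBBLE_PERIOD` positions, as real pre-miRNA stems do; this keeps
    the hairpin stable while making the two arms non-complementary enough
    (>= 2 differences per mature-length window) that arm reads cannot
    cross-map onto the opposite arm.
    """
    L = cfg.precursor_length
    loop_len = L - 2 * ((L - 14) // 2)  # 14 or 15
    stem = (L - loop_len) // 2
    # GC-biased stem for a robustly stable helix
    x = list(rng.choice(_BASES, size=stem, p=[0.2, 0.3, 0.3, 0.2]))
    loop = list(rng.choice(np.array(["A", "C"]), size=loop_len))
    arm3 = [b.translate(_COMPLEMENT) for b in reversed(x)]
    forced_x: set[int] = set()  # 0-based stem indices pinned by events

    def force(pos: int, base: str) -> None:
        # set precursor position `pos` (1-based) to `base`, keeping the
        # stem Watson-Crick paired at that rung
        if pos <= stem:
            x[pos - 1] = base
            arm3[stem - pos] = base.translate(_COMPLEMENT)
            forced_x.add(pos - 1)
        elif pos > L - stem:
            i3 = pos - stem - loop_len - 1  # 0-based index into arm3
            arm3[i3] = base
            x[stem - 1 - i3] = base.translate(_COMPLEMENT)
            forced_x.add(stem - 1 - i3)
        else:
            loop[pos - stem - 1] = base

    for ev in cfg.editing_events:
        if ev.precursor_index == index:
            if not 1 <= ev.position <= cfg.mature_length:
                raise ValueError(
                    f"editing event position {ev.position} not covered by a "
                    f"mature arm (mature length {cfg.mature_length})"
                )
            force(
                _precursor_position(L, cfg.mature_length, ev.arm, ev.position),
                ev.ref,
            )
    for ev in cfg.snp_events:
        if ev.precursor_index == index:
            if not 1 <= ev.position <= L:
                raise ValueError(f"SNP position {ev.position} outside precursor")
            force(ev.position, ev.ref)
    for ev in cfg.tail_events:
        # guarantee the tail is non-templated: the bases just past the 5p
        # mature end must differ from the tail's first nucleotide
        if ev.precursor_index == index and ev.tail:
            (_, e5), _ = _mature_spans(L, cfg.mature_length)
            block = "C" if ev.tail[0].upper() != "C" else "G"
            for pos in range(e5 + 1, min(e5 + 2 * cfg.end_jitter + 1, stem) + 1):
                force(pos, block)
    # G·U wobbles: where the 5p base is G or U, pair it with U or G instead
    # of the Watson-Crick partner (skipping event-pinned rungs)
    for q in range(WOBBLE_PERIOD // 2, stem, WOBBLE_PERIOD):
        if q in forced_x:
            continue
        if x[q] == "G":
            arm3[stem - 1 - q] = "T"
        elif x[q] == "T":
            arm3[stem - 1 - q] = "G"
        else:
            x[q] = "G"
            arm3[stem - 1 - q] = "T"
    return "".join(x) + "".join(loop) + "".join(arm3)


def build_genome(cfg: SimulationConfig) -> tuple[dict[str, str], TruthManifest]:
    """Assemble the toy genome and the locus part of the truth manifest.

    Precursors are placed left to right with ``cfg.spacing`` random bases
    between loci, alternating between the + and − genome strands (the RNA is
    always the precursor sense sequence). Decoy loci are shuffles of
    precursor-like sequences re-drawn until they fail the hairpin gates.
    """
    n_total = cfg.n_precursors + cfg.n_decoys
    footprint = n_total * (cfg.precursor_length + cfg.spacing) + cfg.spacing
    if footprint > cfg.genome_length:
        raise ValueError(
            f"genome_length {cfg.genome_length} too small for {n_total} loci "
            f"(needs >= {footprint})"
        )
    rng = np.random.default_rng(cfg.seed)
    truth = TruthManifest()
    parts: list[str] = []
    cursor = 0  # 0-based length assembled so far

    def background(n: int) -> str:
        return "".join(rng.choice(_BASES, size=n))

    for k in range(cfg.n_precursors):
        parts.append(background(cfg.spacing))
        cursor += cfg.spacing
        seq = _build_precursor(cfg, rng, k)
        strand = "+" if k % 2 == 0 else "-"
        start = cursor + 1
        end = cursor + len(seq)
        parts.append(seq if strand == "+" else reverse_complement(seq))
        cursor = end
        pid = f"sim-mir-{k}"
        m5, m3 = _mature_spans(cfg.precursor_length, cfg.mature_length)
        truth.precursors.append(
            PlantedPrecursor(
                id=pid,
                sequence=seq,
                locus=GenomicLocus(cfg.chrom, start, end, strand, id=pid),
                mature5p=m5,
                mature3p=m3,
            )
        )
        for ev in cfg.editing_events:
            if ev.precursor_index == k:
                pos = _precursor_position(
                    cfg.precursor_length, cfg.mature_length, ev.arm, ev.position
                )
                truth.sites.append(
                    PlantedSite(pid, pos, ev.ref.upper(), ev.alt.upper(),
                                ev.level, "edit", ev.arm, ev.position)
                )
        for ev in cfg.snp_events:
            if ev.precursor_index == k:
                m_pos = arm = None
                for a, (s, e) in (("5p", m5), ("3p", m3)):
                    if s <= ev.position <= e:
                        arm, m_pos = a, ev.position - s + 1
                truth.sites.append(
                    PlantedSite(pid, ev.position, ev.ref.upper(),
                                ev.alt.upper(), 1.0, "snp", arm or "none", m_pos)
                )
                if strand == "+":
                    gpos = start + ev.position - 1
                    gref, galt = ev.ref.upper(), ev.alt.upper()
                else:
                    gpos = end - ev.position + 1
                    gref = ev.ref.upper().translate(_COMPLEMENT)
                    galt = ev.alt.upper().translate(_COMPLEMENT)
                truth.snp_table.append(
                    (cfg.chrom, gpos, gref, galt, f"rs_sim_{k}_{ev.position}")
                )
        for ev in cfg.tail_events:
            if ev.precursor_index == k:
                truth.tails.append(ev)

    for d in range(cfg.n_decoys):
        parts.append(background(cfg.spacing))
        cursor += cfg.spacing
        for _attempt in range(50):
            letters = rng.permutation(list(_build_precursor(cfg, rng, -1)))
            seq = "".join(letters)
            ok, _ = check_hairpin_criteria(fold_hairpin(seq), HairpinCriteria())
            if not ok:
                break
        start, end = cursor + 1, cursor + len(seq)
        parts.append(seq)
        cursor = end
        did = f"sim-decoy-{d}"
        truth.precursors.append(
            PlantedPrecursor(
                id=did,
                sequence=seq,
                locus=GenomicLocus(cfg.chrom, start, end, "+", id=did),
                mature5p=(0, 0),
                mature3p=(0, 0),
                is_decoy=True,
            )
        )

    parts.append(background(cfg.genome_length - cursor))
    return {cfg.chrom: "".join(parts)}, truth


def simulate_profile(
    cfg: SimulationConfig, truth: TruthManifest
) -> list[SimulatedRead]:
    """Simulate one sequencing profile; appends provenance to ``truth``.

    Reads are drawn from both mature arms of every non-decoy precursor with
    independent uniform end jitter on {−2..+2}, truncated to the precursor.
    Planted edits are applied per read with probability equal to the true
    level; SNP alts always; tails with their configured fraction.
    Per-base sequencing errors hit the insert with probability 10^(−Q/10);
    the 3' adapter is then appended error-free. Quality strings are constant
    at ``cfg.base_quality``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    err_p = 10.0 ** (-cfg.base_quality / 10.0)
    reads: list[SimulatedRead] = []
    serial = 0
    edits_by_precursor: dict[str, list[PlantedSite]] = {}
    for s in truth.sites:
        edits_by_precursor.setdefault(s.precursor_id, []).append(s)
    tails_by_precursor: dict[str, list[TailEvent]] = {}
    for i, p in enumerate([q for q in truth.precursors if not q.is_decoy]):
        for t in truth.tails:
            if t.precursor_index == i:
                tails_by_precursor.setdefault(p.id, []).append(t)

    for prec in truth.precursors:
        if prec.is_decoy:
            continue
        L = len(prec.sequence)
        for arm, (ms, me) in (("5p", prec.mature5p), ("3p", prec.mature3p)):
            for _ in range(cfg.coverage_per_mature):
                start = int(ms + rng.integers(-cfg.end_jitter, cfg.end_jitter + 1))
                end = int(me + rng.integers(-cfg.end_jitter, cfg.end_jitter + 1))
                start = max(1, start)
                end = min(L, max(end, start + 1))
                bases = list(prec.sequence[start - 1 : end])
                applied: list[int] = []
                for site in edits_by_precursor.get(prec.id, []):
                    if start <= site.position <= end:
                        hit = site.kind == "snp" or rng.random() < site.level
                        if hit:
                            bases[site.position - start] = site.alt
                            applied.append(site.position)
                tail = ""
                for tev in tails_by_precursor.get(prec.id, []):
                    if rng.random() < tev.fraction:
                        tail = tev.tail.upper()
                        break
                # per-base sequencing errors on the insert
                n_err = 0
                for b in range(len(bases)):
                    if rng.random() < err_p:
                        alt = rng.choice(
                            [c for c in "ACGT" if c != bases[b]]
                        )
                        bases[b] = str(alt)
                        n_err += 1
                insert = "".join(bases) + tail
                serial += 1
                rid = f"r{serial:06d}"
                truth.reads.append(
                    ReadProvenance(
                        read_id=rid,
                        precursor_id=prec.id,
                        arm=arm,
                        start=start,
                        end=end,
                        edits_applied=tuple(applied),
                        tail_applied=tail,
                        n_errors=n_err,
                        sequence=insert,
                    )
                )
                reads.append(
                    SimulatedRead(
                        id=rid,
                        sequence=insert + cfg.adapter,
                        quality=cfg.base_quality,
                    )
                )
    return reads


def write_fastq(reads: list[SimulatedRead], path: str | Path) -> None:
    """Write simulated reads as Phred+33 FASTQ (byte-deterministic)."""
    with open(path, "w") as fh:
        for r in reads:
            q = chr(r.quality + 33) * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{q}\n")


def reads_as_fastq_records(reads: list[SimulatedRead]):
    """Adapter-level view used by the preprocessing stage (no file round
    trip needed in-memory)."""
    from .sequence_io import FastqRecord

    return [
        FastqRecord(r.id, r.sequence, tuple([r.quality] * len(r.sequence)))
        for r in reads
    ]


# ---------------------------------------------------------------------------
# discovery study: one genuine novel precursor plus single-clause decoys
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscoveryStudy:
    """A genome and read profile for exercising de-novo discovery gates.

    ``expected_id`` is the genuine precursor's candidate locus id;
    ``decoy_clauses`` maps each decoy's candidate id to the single filter
    clause its design violates (the paired-count decoy necessarily also
    misses the energy gate — no hairpin below the energy threshold can have
    fewer than 18 paired nucleotides).
    """

    genome: dict[str, str]
    profile: list["FastqRecord"]
    expected_id: str
    decoy_clauses: dict[str, str]
    accumulation_truth: dict[str, float]


def _ac_background(rng: np.random.Generator, n: int) -> str:
    # A/C-only background cannot base-pair (no G or U partner present),
    # so candidate windows fold on the planted locus alone
    return "".join(rng.choice(np.array(["A", "C"]), size=n))


def build_discovery_study(seed: int = 0) -> DiscoveryStudy:
    """Genome + profile with one genuine novel precursor and four decoys.

    The genuine locus has a stable wobbled hairpin, 72% read accumulation in
    the mature regions and 2-nt 3' overhangs. Decoys: a weak A/U-stem
    hairpin (energy clause), a short 8-pair stem (paired-count clause, which
    on any physical energy scale also entails the energy clause), twin
    strong stems (terminal-loop-count clause), a good hairpin with 64%
    accumulation, and a good hairpin supported by only 9 reads.
    """
    from .sequence_io import FastqRecord

    rng = np.random.default_rng(seed)
    adapter = DEFAULT_ADAPTER
    base_cfg = SimulationConfig(genome_length=10_000, n_precursors=1,
                                seed=seed)

    def hairpin(salt: int) -> str:
        sub = np.random.default_rng(seed * 1000 + salt)
        for _ in range(20):
            seq = _build_precursor(base_cfg, sub, -1)
            reads = [seq[2:24], seq[58:80], seq[29:51]]
            if all("TGGAAT" not in r for r in reads):
                return seq
        raise AssertionError("could not build adapter-free hairpin")

    good = hairpin(1)
    acc_decoy = hairpin(2)
    low_decoy = hairpin(3)

    # energy decoy: A/U stem folds but far above the energy gate
    for _ in range(20):
        x = "".join(rng.choice(np.array(["A", "T"]), size=25))
        energy_decoy = x + "CCCCCC" + reverse_complement(x)
        if "TGGAAT" not in energy_decoy:
            break

    # paired-count decoy: strong but short stem (8 pairs = 16 paired nt)
    x8 = "GCCGTGGC"
    pairs_decoy = x8 + "AACCAA" + reverse_complement(x8)

    # loop-count decoy: two strong stems side by side
    def strong_stem(sub_rng):
        y = "".join(sub_rng.choice(_BASES, size=16, p=[0.1, 0.4, 0.4, 0.1]))
        return y + "CAACA" + reverse_complement(y)

    for _ in range(50):
        loops_decoy = strong_stem(rng) + "AACCA" + strong_stem(rng)
        if "TGGAAT" not in loops_decoy:
            break

    spacer = 200
    loci: list[tuple[str, str]] = [
        ("good", good),
        ("energy", energy_decoy),
        ("pairs", pairs_decoy),
        ("loops", loops_decoy),
        ("acc", acc_decoy),
        ("low", low_decoy),
    ]
    genome_parts = []
    cursor = 0
    starts: dict[str, int] = {}
    for name, seq in loci:
        genome_parts.append(_ac_background(rng, spacer))
        cursor += spacer
        starts[name] = cursor + 1
        genome_parts.append(seq)
        cursor += len(seq)
    genome_parts.append(_ac_background(rng, spacer))
    genome = {"chrD": "".join(genome_parts)}

    def records(name: str, insert: str, count: int) -> list:
        return [
            FastqRecord(f"{name}-{i}", insert + adapter,
                        tuple([40] * (len(insert) + len(adapter))))
            for i in range(count)
        ]

    profile: list = []
    # genuine precursor: 36+36 mature reads, 28 loop reads -> 72% accumulation
    profile += records("good-m5", good[2:24], 36)
    profile += records("good-m3", good[58:80], 36)
    profile += records("good-loop", good[29:51], 28)
    # energy decoy: clean accumulation, mature-analog spans with 2-nt overhangs
    profile += records("energy-m5", energy_decoy[2:24], 50)
    profile += records("energy-m3", energy_decoy[34:56], 50)
    # paired-count decoy: the whole 22-nt locus as one abundant read
    profile += records("pairs-read", pairs_decoy, 50)
    # loop decoy: one abundant read per stem
    profile += records("loops-r1", loops_decoy[0:20], 50)
    profile += records("loops-r2", loops_decoy[len(loops_decoy) - 20 :], 50)
    # accumulation decoy: 64% of reads in the mature regions (loop reads
    # split across two sequences so neither outnumbers the mature reads)
    profile += records("acc-m5", acc_decoy[2:24], 32)
    profile += records("acc-m3", acc_decoy[58:80], 32)
    profile += records("acc-loop1", acc_decoy[28:47], 18)
    profile += records("acc-loop2", acc_decoy[31:50], 18)
    # low-abundance decoy: 9 reads total
    profile += records("low-m5", low_decoy[2:24], 5)
    profile += records("low-m3", low_decoy[58:80], 4)

    flank = 80

    def cid(name: str, read_offset: int) -> str:
        return f"novel-chrD-{max(1, starts[name] + read_offset - flank)}-+"

    return DiscoveryStudy(
        genome=genome,
        profile=profile,
        expected_id=cid("good", 2),
        decoy_clauses={
            cid("energy", 2): "energy",
            cid("pairs", 0): "min_paired",
            cid("loops", 0): "loop_count",
            cid("acc", 2): "accumulation",
            cid("low", 2): "min_total_reads",
        },
        accumulation_truth={cid("good", 2): 0.72, cid("acc", 2): 0.64},
    )
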