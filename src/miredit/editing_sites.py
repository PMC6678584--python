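"""Identification, significance testing and classification of
mutation/editing (M/E) sites in miRNA precursors.

Per precursor position, cross-map-weighted read support for every
alternative nucleotide is tallied against the reference
(:func:`tally_variants`); each candidate is tested against a sequencing-error
null with a one-sided exact binomial tail (:func:`test_site`), corrected for
multiple testing per sample (Benjamini–Hochberg), and gated by the standard
significance criteria: editing level ≥ 5%, support ≥ 10 reads, base quality
threshold 30, corrected p < 0.05 (:func:`adjust_and_filter`).

Significant sites are classified into the canonical categories — 3'-A, 3'-U,
3'-Other (non-templated tailing), 5' site, A-to-I, C-to-U, Other, SNP and
Pseudo (cross-mapping artifact). SNPs are assigned only by comparison with a
variant table (:func:`call_snps`): same genomic position, same alleles, and a
100% level in at least one sample. Site identifiers follow the
``{precursor}_{position}_{REF}_{alt}`` convention with the reference
uppercase and the alternative lowercase, in RNA alphabet (e.g.
``mml-mir-376c_48_A_g``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mirna_discovery import Precursor
from .read_alignment import PrecursorAlignment

CATEGORIES = (
    "3'-A", "3'-U", "3'-Other", "5' site", "A-to-I", "C-to-U",
    "Other", "SNP", "Pseudo",
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _rna(nt: str) -> str:
    return nt.upper().replace("T", "U")


@dataclass(frozen=True)
class EditingConfig:
    """Significance criteria for M/E sites.

    ``per_base_error`` is the probability of one specific erroneous
    substitution at a base passing the quality gate: an error occurs with
    probability 10^(−Q/10) and lands on one of three alternatives.
    """

    min_level: float = 0.05
    min_support: float = 10.0
    q_threshold: int = 30
    alpha: float = 0.05
    per_base_error: float | None = None
    pseudo_weight_threshold: float = 0.5
    five_prime_shift: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.min_level < 1:
            raise ValueError("min_level must be in (0, 1)")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")

    @property
    def error_rate(self) -> float:
        if self.per_base_error is not None:
            return self.per_base_error
        return 10.0 ** (-self.q_threshold / 10.0) / 3.0


@dataclass(frozen=True)
class SNPRecord:
    chrom: str
    position: int  # 1-based genomic
    ref: str
    alt: str
    rsid: str = ""

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("SNP alleles must be single nucleotides")


@dataclass(frozen=True)
class MESite:
    """One candidate mutation/editing site in one sample."""

    precursor_id: str
    position: int  # 1-based on precursor
    ref: str
    alt: str
    support: float  # cross-map weighted alt reads
    depth: float  # weighted reads covering the position
    p_value: float = 1.0
    p_adjusted: float = 1.0
    category: str = "Other"
    sample_id: str = ""
    mature_position: int | None = None
    is_tail: bool = False
    subtype: str = ""

    def __post_init__(self) -> None:
        if self.support > self.depth + 1e-9:
            raise ValueError("support cannot exceed depth")

    @property
    def level(self) -> float:
        return self.support / self.depth if self.depth > 0 else 0.0

    @property
    def site_id(self) -> str:
        return (
            f"{self.precursor_id}_{self.position}_"
            f"{_rna(self.ref)}_{_rna(self.alt).lower()}"
        )


@dataclass
class PositionTally:
    position: int
    ref: str
    depth: float = 0.0
    alts: dict[str, float] = field(default_factory=dict)
    tail_alts: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# tallying
# ---------------------------------------------------------------------------

def tally_variants(
    alignments: Sequence[PrecursorAlignment],
    precursor: Precursor,
    weights: Mapping[str, float] | None = None,
) -> dict[int, PositionTally]:
    """Weighted per-position depth and per-alternative support.

    ``weights`` maps read sequence to this precursor's cross-map weight
    (default 1). Templated bases add to depth at every covered position and
    to alt support where they mismatch the reference; soft-tail bases are
    tallied separately per tail nucleotide at the positions just past the
    templated end (positions beyond the precursor terminus have no reference
    base and are not tallied as sites).
    """
    seq = precursor.sequence
    tallies: dict[int, PositionTally] = {}

    def at(pos: int) -> PositionTally:
        if pos not in tallies:
            tallies[pos] = PositionTally(position=pos, ref=seq[pos - 1])
        return tallies[pos]

    for a in alignments:
        if a.precursor_id != precursor.id:
            continue
        w = (weights.get(a.read.sequence, 1.0) if weights else 1.0) * a.read.count
        if w <= 0:
            continue
        for pos in range(a.offset, a.templated_end + 1):
            if not 1 <= pos <= len(seq):
                continue
            t = at(pos)
            t.depth += w
            read_nt = a.read.sequence[pos - a.offset]
            if read_nt != seq[pos - 1]:
                t.alts[read_nt] = t.alts.get(read_nt, 0.0) + w
        for i, nt in enumerate(a.soft_tail):
            pos = a.templated_end + 1 + i
            if not 1 <= pos <= len(seq):
                continue
            t = at(pos)
            t.depth += w
            t.tail_alts[nt] = t.tail_alts.get(nt, 0.0) + w
    return tallies


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def test_site(support: float, depth: float, cfg: EditingConfig | None = None) -> float:
    """One-sided exact binomial tail P(X >= ceil(support)) under the
    sequencing-error null, X ~ Binomial(round(depth), per_base_error).

    Fractional weighted support is rounded up (conservative); depth is
    rounded to the nearest integer.
    """
    cfg = cfg or EditingConfig()
    n = int(round(depth))
    if n < 1:
        raise ValueError("depth must be >= 1")
    k = math.ceil(support - 1e-9)
    if k > n:
        raise ValueError(f"support {support} exceeds depth {n}")
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, cfg.error_rate))


def sites_from_tallies(
    tallies: Mapping[int, PositionTally],
    precursor: Precursor,
    sample_id: str = "",
    cfg: EditingConfig | None = None,
) -> list[MESite]:
    """Materialize per-(position, alternative) candidate sites with raw
    binomial p-values (no filtering)."""
    cfg = cfg or EditingConfig()
    out = []
    for pos in sorted(tallies):
        t = tallies[pos]
        if t.depth <= 0:
            continue
        for is_tail, alts in ((False, t.alts), (True, t.tail_alts)):
            for alt in sorted(alts):
                support = alts[alt]
                site = MESite(
                    precursor_id=precursor.id,
                    position=pos,
                    ref=t.ref,
                    alt=alt,
                    support=support,
                    depth=t.depth,
                    p_value=test_site(min(support, t.depth), t.depth, cfg),
                    sample_id=sample_id,
                    mature_position=_mature_position(precursor, pos),
                    is_tail=is_tail,
                )
                out.append(site)
    return out


def adjust_and_filter(
    sites: Sequence[MESite], cfg: EditingConfig | None = None
) -> list[MESite]:
    """Benjamini–Hochberg across all candidate tests within one sample, then
    keep sites with level >= min_level, support >= min_support and corrected
    p < alpha."""
    cfg = cfg or EditingConfig()
    if not sites:
        return []
    pvals = np.array([s.p_value for s in sites])
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    kept = []
    for site, pa in zip(sites, p_adj):
        site = replace(site, p_adjusted=float(pa))
        if (
            site.level >= cfg.min_level
            and site.support >= cfg.min_support
            and site.p_adjusted < cfg.alpha
        ):
            kept.append(site)
    return kept


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _mature_position(precursor: Precursor, position: int) -> int | None:
    for s, e in precursor.matures.values():
        if s <= position <= e:
            return position - s + 1
    return None


def _arm_of(precursor: Precursor, position: int) -> tuple[str, tuple[int, int]] | None:
    for arm, (s, e) in precursor.matures.items():
        if s <= position <= e:
            return arm, (s, e)
    return None


def classify_site(
    site: MESite,
    precursor: Precursor,
    cross_weight_elsewhere: float = 0.0,
    cfg: EditingConfig | None = None,
) -> MESite:
    """Assign one category to a significant site.

    Decision order: cross-mapping artifact (Pseudo) when the supporting
    reads' majority origin is another locus; non-templated 3' tailing by
    tail nucleotide (A → 3'-A, U → 3'-U, else 3'-Other); substitutions at or
    just 5' of the mature start (5' site); canonical central editing
    (A-to-I, C-to-U); any other substitution (Other, with the substitution
    subtype recorded). SNP status is assigned only by :func:`call_snps`.
    """
    cfg = cfg or EditingConfig()
    subtype = f"{_rna(site.ref)}-to-{_rna(site.alt)}"
    if cross_weight_elsewhere >= cfg.pseudo_weight_threshold:
        cat = "Pseudo"
    elif site.is_tail:
        nt = _rna(site.alt)
        cat = {"A": "3'-A", "U": "3'-U"}.get(nt, "3'-Other")
    else:
        near_5p = False
        for arm, (s, e) in precursor.matures.items():
            if s - cfg.five_prime_shift <= site.position <= s:
                near_5p = True
        if near_5p:
            cat = "5' site"
        elif site.ref.upper() == "A" and site.alt.upper() == "G":
            cat = "A-to-I"
        elif site.ref.upper() == "C" and site.alt.upper() == "T":
            cat = "C-to-U"
        else:
            cat = "Other"
    return replace(
        site,
        category=cat,
        subtype=subtype,
        mature_position=_mature_position(precursor, site.position),
    )


# ---------------------------------------------------------------------------
# SNP calling
# ---------------------------------------------------------------------------

def precursor_to_genomic(precursor: Precursor, position: int) -> tuple[str, int]:
    """Map a 1-based precursor position to (chrom, genomic position)."""
    loc = precursor.locus
    if loc is None:
        raise ValueError(f"precursor {precursor.id} lacks a genomic locus")
    if loc.strand == "+":
        return loc.chrom, loc.start + position - 1
    return loc.chrom, loc.end - position + 1


def call_snps(
    sites: Sequence[MESite],
    snp_table: Sequence[SNPRecord],
    precursors: Mapping[str, Precursor],
) -> list[MESite]:
    """Re-label sites as SNP when all three clauses hold: (i) the genomic
    position matches an annotated SNP, (ii) both alleles match (strand-aware
    complementing for − strand precursors), and (iii) the site reaches a
    100% level in at least one sample. Returns a new site list; sites on
    precursors without a genomic locus are left unchanged."""
    snp_index: dict[tuple[str, int], list[SNPRecord]] = {}
    for rec in snp_table:
        snp_index.setdefault((rec.chrom, rec.position), []).append(rec)
    max_level: dict[str, float] = {}
    for s in sites:
        max_level[s.site_id] = max(max_level.get(s.site_id, 0.0), s.level)
    out = []
    for s in sites:
        prec = precursors.get(s.precursor_id)
        if prec is None or prec.locus is None:
            out.append(s)
            continue
        chrom, gpos = precursor_to_genomic(prec, s.position)
        ref, alt = s.ref.upper(), s.alt.upper()
        if prec.locus.strand == "-":
            ref = ref.translate(_COMPLEMENT)
            alt = alt.translate(_COMPLEMENT)
        matched = any(
            rec.ref.upper() == ref and rec.alt.upper() == alt
            for rec in snp_index.get((chrom, gpos), ())
        )
        if matched and max_level[s.site_id] >= 1.0 - 1e-9:
            s = replace(s, category="SNP")
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# sample combination and cross-species matching
# ---------------------------------------------------------------------------

@dataclass
class CombinedSites:
    levels: pd.DataFrame  # site_id x sample_id, NaN where not covered
    info: pd.DataFrame  # per-site metadata and detection flags


def combine_samples(
    per_sample: Iterable[tuple[str, Sequence[MESite]]],
    sample_tissue: Mapping[str, str] | None = None,
    significant_ids: Mapping[str, set[str]] | None = None,
) -> CombinedSites:
    """Union sites across samples into a site × sample level matrix.

    ``significant_ids`` optionally maps sample id to the set of site_ids
    that passed the significance gates in that sample, to distinguish
    detection from significance. Duplicate sample ids are an error.
    """
    seen_samples: list[str] = []
    cells: dict[tuple[str, str], float] = {}
    meta: dict[str, MESite] = {}
    detected: dict[str, set[str]] = {}
    for sample_id, sites in per_sample:
        if sample_id in seen_samples:
            raise ValueError(f"duplicate sample id {sample_id!r}")
        seen_samples.append(sample_id)
        for s in sites:
            cells[(s.site_id, sample_id)] = s.level
            meta.setdefault(s.site_id, s)
            detected.setdefault(s.site_id, set()).add(sample_id)
    if not cells:
        return CombinedSites(
            levels=pd.DataFrame(), info=pd.DataFrame()
        )
    site_ids = sorted(meta)
    levels = pd.DataFrame(
        np.nan, index=site_ids, columns=seen_samples, dtype=float
    )
    for (sid, samp), lvl in cells.items():
        levels.loc[sid, samp] = lvl
    rows = []
    for sid in site_ids:
        s = meta[sid]
        n_det = len(detected[sid])
        n_sig = (
            sum(1 for samp in seen_samples
                if sid in significant_ids.get(samp, set()))
            if significant_ids is not None
            else n_det
        )
        tissues = sorted(
            {sample_tissue.get(samp, samp) for samp in detected[sid]}
        ) if sample_tissue else sorted(detected[sid])
        rows.append(
            {
                "site_id": sid,
                "precursor_id": s.precursor_id,
                "position": s.position,
                "ref": _rna(s.ref),
                "alt": _rna(s.alt).lower(),
                "category": s.category,
                "mature_position": s.mature_position,
                "n_samples_detected": n_det,
                "n_samples_significant": n_sig,
                "tissues": ",".join(tissues),
            }
        )
    info = pd.DataFrame(rows).set_index("site_id")
    return CombinedSites(levels=levels, info=info)


def normalize_family_key(precursor_id: str) -> str:
    """Normalize a precursor id to a cross-species family key.

    Strips the species prefix (e.g. ``mml-``, ``hsa-``) and a trailing
    paralog copy suffix (``-1``, ``-2``): ``mml-mir-376a-1`` and
    ``hsa-mir-376a-2`` both map to ``mir-376a``.
    """
    key = precursor_id.lower()
    parts = key.split("-")
    if parts and len(parts[0]) in (3, 4) and parts[0] not in {"mir", "let"}:
        parts = parts[1:]
    if len(parts) > 2 and parts[-1].isdigit():
        parts = parts[:-1]
    return "-".join(parts)


def match_conserved_sites(
    sites_a: Sequence[MESite],
    sites_b: Sequence[MESite],
) -> list[tuple[MESite, MESite]]:
    """Pair sites across species sharing miRNA family, mature position and
    substitution — conserved editing despite different precursor lengths.
    Sites without a mature position cannot match."""
    index: dict[tuple[str, int, str, str], list[MESite]] = {}
    for b in sites_b:
        if b.mature_position is None:
            continue
        key = (
            normalize_family_key(b.precursor_id),
            b.mature_position,
            _rna(b.ref),
            _rna(b.alt),
        )
        index.setdefault(key, []).append(b)
    out = []
    for a in sites_a:
        if a.mature_position is None:
            continue
        key = (
            normalize_family_key(a.precursor_id),
            a.mature_position,
            _rna(a.ref),
            _rna(a.alt),
        )
        for b in index.get(key, ()):
            out.append((a, b))
    return out


def sites_to_table(sites: Sequence[MESite]) -> pd.DataFrame:
    """Fixed-column site table (one row per site per sample)."""
    rows = [
        {
            "site_id": s.site_id,
            "precursor_id": s.precursor_id,
            "position": s.position,
            "ref": _rna(s.ref),
            "alt": _rna(s.alt).lower(),
            "category": s.category,
            "level": s.level,
            "support": s.support,
            "depth": s.depth,
            "p_value": s.p_value,
            "p_adjusted": s.p_adjusted,
            "sample_id": s.sample_id,
            "mature_position": s.mature_position,
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "site_id", "precursor_id", "position", "ref", "alt", "category",
            "level", "support", "depth", "p_value", "p_adjusted", "sample_id",
            "mature_position",
        ],
    )
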