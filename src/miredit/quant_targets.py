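"""miRNA expression quantification, seed-match target prediction and
target-set comparison for original versus edited/mutated miRNAs.

Expression is reported in RPTM (reads per ten million): a mature miRNA's
cross-map-weighted read count scaled by 10^7 over the total reads mapped to
the mature miRNA set in that sample. Expressed miRNAs are those with mean
RPTM >= 5 and sample standard deviation >= 1 across profiles.

Targets are 3'UTR windows pairing the miRNA seed: scanning the UTR, a window
is a target when at least seven consecutive Watson–Crick pairs (G:U wobble
not counted) form against miRNA positions 1–8, necessarily covering the seed
(positions 2–8). Editing a seed position therefore rewires the predicted
target set, which :func:`compare_target_sets` quantifies as the percentage
of shared transcripts. Term enrichment of target genes is a hypergeometric
upper tail over a user-supplied term → gene annotation, BH-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .editing_sites import MESite

RPTM_SCALE = 10_000_000
SEED_SPAN = 8  # miRNA positions 1-8 participate in seed pairing
MIN_SEED_RUN = 7

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


@dataclass(frozen=True)
class ExpressionRecord:
    mature_id: str
    sample_id: str
    count: float
    rptm: float

    def __post_init__(self) -> None:
        if self.rptm < 0 or (self.rptm == 0) != (self.count == 0):
            raise ValueError("rptm must be >= 0 and zero iff count is zero")


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    utr_position: int  # 1-based start of the paired window on the UTR
    match_run: int

    def __post_init__(self) -> None:
        if self.match_run < MIN_SEED_RUN:
            raise ValueError("matched run must be >= 7")


@dataclass(frozen=True)
class SetComparison:
    size_a: int
    size_b: int
    intersection: int
    percent_shared: float  # 100 * |A ∩ B| / |A ∪ B|


def compute_rptm(
    counts: Mapping[str, float], sample_id: str, total: float | None = None
) -> list[ExpressionRecord]:
    """RPTM per mature miRNA; ``total`` defaults to the sum of ``counts``
    (reads mapped to the mature set in this sample)."""
    denom = float(total) if total is not None else float(sum(counts.values()))
    if denom <= 0:
        raise ValueError("sample total must be > 0")
    return [
        ExpressionRecord(
            mature_id=mid,
            sample_id=sample_id,
            count=float(c),
            rptm=float(c) * RPTM_SCALE / denom,
        )
        for mid, c in sorted(counts.items())
    ]


def select_expressed(
    records: Iterable[ExpressionRecord],
    min_mean: float = 5.0,
    min_sd: float = 1.0,
) -> set[str]:
    """Matures with mean RPTM >= ``min_mean`` and sample standard deviation
    (n−1 denominator) >= ``min_sd`` across samples."""
    by_mature: dict[str, list[float]] = {}
    for r in records:
        by_mature.setdefault(r.mature_id, []).append(r.rptm)
    n_samples = max((len(v) for v in by_mature.values()), default=0)
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    out = set()
    for mid, vals in by_mature.items():
        arr = np.asarray(vals, dtype=float)
        if arr.mean() >= min_mean and arr.std(ddof=1) >= min_sd:
            out.add(mid)
    return out


def apply_edit(mature_sequence: str, site: MESite) -> str:
    """Apply a single-nucleotide M/E event to a mature sequence.

    The site's mature-relative position must carry the reference nucleotide
    (re-applying an edit raises); A-to-I events substitute G, since inosine
    is read as guanosine.
    """
    if site.mature_position is None:
        raise ValueError(f"site {site.site_id} has no mature position")
    pos = site.mature_position
    seq = mature_sequence.upper()
    is_rna = "U" in seq and "T" not in seq
    dna = seq.replace("U", "T")
    if not 1 <= pos <= len(dna):
        raise ValueError(f"mature position {pos} outside sequence")
    ref = site.ref.upper().replace("U", "T")
    alt = site.alt.upper().replace("U", "T")
    if dna[pos - 1] != ref:
        raise ValueError(
            f"reference mismatch at position {pos}: sequence has "
            f"{dna[pos - 1]}, site expects {ref}"
        )
    edited = dna[: pos - 1] + alt + dna[pos:]
    return edited.replace("T", "U") if is_rna else edited


def _seed_matches(mirna: str, window: str) -> int:
    """Longest run of consecutive Watson–Crick pairs between miRNA positions
    1-8 and an antiparallel 8-nt UTR window (window given 5'->3')."""
    best = run = 0
    for k in range(SEED_SPAN):
        mi = mirna[k]  # miRNA position k+1
        ut = window[SEED_SPAN - 1 - k]  # antiparallel partner
        if (mi, ut) in _WC:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def predict_targets(
    mirna_id: str,
    mature_sequence: str,
    utrs: Mapping[str, str],
) -> list[TargetSite]:
    """All UTR windows with >= 7 consecutive Watson–Crick pairs against
    miRNA positions 1–8 (G:U not counted); every such run necessarily covers
    the seed region (positions 2–8). All windows are reported."""
    seq = mature_sequence.upper().replace("U", "T")
    if len(seq) < SEED_SPAN:
        raise ValueError("mature sequence must be >= 8 nt")
    out = []
    for tid in sorted(utrs):
        utr = utrs[tid].upper().replace("U", "T")
        for start in range(len(utr) - SEED_SPAN + 1):
            window = utr[start : start + SEED_SPAN]
            run = _seed_matches(seq, window)
            if run >= MIN_SEED_RUN:
                out.append(
                    TargetSite(
                        mirna_id=mirna_id,
                        transcript_id=tid,
                        utr_position=start + 1,
                        match_run=run,
                    )
                )
    return out


def compare_target_sets(
    targets_a: Sequence[TargetSite], targets_b: Sequence[TargetSite]
) -> SetComparison:
    """Transcript-level overlap of two target predictions (positions
    collapsed). ``percent_shared`` is the Jaccard percentage; two empty sets
    share 0 by convention."""
    a = {t.transcript_id for t in targets_a}
    b = {t.transcript_id for t in targets_b}
    union = a | b
    inter = a & b
    pct = 100.0 * len(inter) / len(union) if union else 0.0
    return SetComparison(
        size_a=len(a), size_b=len(b), intersection=len(inter),
        percent_shared=pct,
    )


def enrich_sets(
    target_genes: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of each term's gene set within
    the targets, BH-corrected; rows sorted by adjusted p. Terms with empty
    gene sets (after intersecting the universe) are skipped."""
    uni = set(universe)
    targets = set(target_genes) & uni
    if targets - uni:
        raise ValueError("targets must be contained in the universe")
    rows = []
    for term in sorted(annotation):
        term_genes = set(annotation[term]) & uni
        if not term_genes:
            continue
        k = len(targets & term_genes)
        p = float(
            stats.hypergeom.sf(k - 1, len(uni), len(term_genes), len(targets))
        )
        rows.append(
            {
                "term": term,
                "term_size": len(term_genes),
                "overlap": k,
                "n_targets": len(targets),
                "universe": len(uni),
                "p_value": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "term_size", "overlap", "n_targets", "universe",
                     "p_value", "p_adjusted", "significant"]
        )
    df = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(df["p_value"], method="fdr_bh")
    df["p_adjusted"] = p_adj
    df["significant"] = df["p_adjusted"] < alpha
    return df.sort_values(["p_adjusted", "term"]).reset_index(drop=True)
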