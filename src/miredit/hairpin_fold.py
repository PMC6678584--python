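"""Single-hairpin RNA secondary-structure prediction and precursor criteria.

Pre-miRNAs fold into a stem-loop; this module predicts the minimum-free-energy
nested structure of a candidate precursor under a simplified Turner-style
nearest-neighbor model and evaluates the structural gates used to accept a
locus as a genuine precursor:

* a folding-energy / paired-count / single-terminal-loop gate
  (:func:`check_hairpin_criteria`),
* placement quality of the mature miRNA on one stem arm
  (:func:`evaluate_mature_placement`),
* the Dicer signature of a ~2-nt 3' overhang on the mature duplex
  (:func:`check_duplex_overhang`).

Model class
-----------
Structures are nested sets of base pairs (no pseudoknots) in which every pair
encloses at most one directly-nested pair — i.e. unbranched helices ending in
terminal loops, with any number of independent stem-loops side by side at the
outer level. Multiloops are excluded: pre-miRNA hairpins are single stems, and
the restriction keeps the model exhaustively enumerable at small n, which is
how the optimizer is validated.

Energy model
------------
Watson-Crick and G·U wobble pairs are allowed. A pair stacked directly on
another contributes a nearest-neighbor stacking term; a pair closing a
terminal loop pays a length-dependent hairpin penalty; offset nestings pay
bulge / internal-loop penalties. The tables below are approximate Turner-style
free energies at 37 °C in kcal/mol; they are module constants and can be
swapped for another parameter set. Energies are handled internally in integer
hundredths of a kcal/mol so that optimality comparisons are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "HairpinStructure",
    "HairpinCriteria",
    "MatureCriteria",
    "fold_hairpin",
    "structure_energy",
    "check_hairpin_criteria",
    "evaluate_mature_placement",
    "check_duplex_overhang",
    "to_dot_bracket",
    "from_dot_bracket",
]

# allowed base pairs (RNA alphabet; T treated as U)
_PAIRABLE = {"AU", "UA", "CG", "GC", "GU", "UG"}

MIN_HAIRPIN_LOOP = 3  # minimum unpaired bases closed by a pair
MAX_INTERIOR_UNPAIRED = 12  # u1+u2 cap for bulge/internal loops in the DP

# Nearest-neighbor stacking free energies, kcal/mol.
# Key: (closing pair 5'i-j3', inner pair 5'i+1-j-1 3').
STACKING = {
    ("AU", "AU"): -0.93, ("AU", "CG"): -2.24, ("AU", "GC"): -2.08,
    ("AU", "UA"): -1.10, ("AU", "GU"): -1.36, ("AU", "UG"): -0.55,
    ("CG", "AU"): -2.11, ("CG", "CG"): -3.26, ("CG", "GC"): -2.36,
    ("CG", "UA"): -2.08, ("CG", "GU"): -2.11, ("CG", "UG"): -1.41,
    ("GC", "AU"): -2.24, ("GC", "CG"): -3.42, ("GC", "GC"): -3.26,
    ("GC", "UA"): -2.35, ("GC", "GU"): -2.51, ("GC", "UG"): -1.53,
    ("UA", "AU"): -1.33, ("UA", "CG"): -2.24, ("UA", "GC"): -2.11,
    ("UA", "UA"): -0.93, ("UA", "GU"): -1.27, ("UA", "UG"): -1.00,
    ("GU", "AU"): -1.27, ("GU", "CG"): -2.51, ("GU", "GC"): -2.11,
    ("GU", "UA"): -1.36, ("GU", "GU"): -0.50, ("GU", "UG"): 1.29,
    ("UG", "AU"): -1.00, ("UG", "CG"): -1.53, ("UG", "GC"): -1.41,
    ("UG", "UA"): -0.55, ("UG", "GU"): 0.30, ("UG", "UG"): -0.50,
}

# hairpin-loop initiation penalties by loop size (kcal/mol)
_HAIRPIN_PENALTY = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
# bulge-loop penalties by total unpaired count
_BULGE_PENALTY = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
# internal-loop penalties by total unpaired count (both sides >= 1)
_INTERNAL_PENALTY = {2: 1.0, 3: 2.0, 4: 2.1, 5: 2.3, 6: 2.5}
_JACOBSON = 1.08  # kcal/mol prefactor for logarithmic loop extrapolation


def _loop_extrapolate(table: dict[int, float], size: int) -> float:
    base = max(table)
    if size <= base:
        return table[size]
    return table[base] + _JACOBSON * math.log(size / base)


def hairpin_penalty(size: int) -> float:
    if size < MIN_HAIRPIN_LOOP:
        raise ValueError(f"hairpin loop of size {size} < {MIN_HAIRPIN_LOOP}")
    return _loop_extrapolate(_HAIRPIN_PENALTY, size)


def interior_penalty(u1: int, u2: int) -> float:
    """Bulge (one side empty) or internal-loop penalty, by unpaired total."""
    u = u1 + u2
    if u < 1:
        raise ValueError("interior loop must have unpaired bases")
    if u1 == 0 or u2 == 0:
        return _loop_extrapolate(_BULGE_PENALTY, u)
    return _loop_extrapolate(_INTERNAL_PENALTY, max(u, 2))


def _normalize(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


def _pairable(seq: str, i: int, j: int) -> bool:
    return seq[i] + seq[j] in _PAIRABLE


@dataclass(frozen=True)
class HairpinStructure:
    """A nested secondary structure with its free energy.

    ``pairs`` are 0-based (i, j) index pairs, i < j. ``n_loops`` counts
    terminal (hairpin) loops; a clean pre-miRNA stem-loop has exactly one.
    """

    pairs: frozenset[tuple[int, int]]
    energy: float
    n_loops: int
    length: int

    @property
    def paired_count(self) -> int:
        return 2 * len(self.pairs)

    def partner_map(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


@dataclass(frozen=True)
class HairpinCriteria:
    """Acceptance gates for a candidate precursor structure.

    Defaults follow the standard stringent annotation rule: folding energy
    below −40 kcal/mol, at least 18 paired nucleotides, and a single terminal
    loop. ``mfe_max`` is interpreted on this module's energy scale and is
    configurable.
    """

    mfe_max: float = -40.0
    min_paired: int = 18
    max_loops: int = 1

    def __post_init__(self) -> None:
        if self.mfe_max >= 0:
            raise ValueError("mfe_max must be negative")


@dataclass(frozen=True)
class MatureCriteria:
    """Mature-placement quality gates on the precursor stem."""

    max_bulged: int = 2
    max_mismatch_or_asym: int = 5
    max_continuous_mismatch: int = 3


# ---------------------------------------------------------------------------
# energy of an explicit structure (shared definition, used by the optimizer
# and by enumeration-based validation)
# ---------------------------------------------------------------------------

def _children_map(
    pairs: Iterable[tuple[int, int]]
) -> dict[tuple[int, int] | None, list[tuple[int, int]]]:
    """Direct-nesting forest of a nested pair set; raises on crossing pairs
    or multi-branch (more than one child per pair)."""
    sorted_pairs = sorted(pairs)
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    seen: set[int] = set()
    for p in sorted_pairs:
        i, j = p
        if i >= j:
            raise ValueError(f"pair {p} not (i < j)")
        if j - i <= MIN_HAIRPIN_LOOP:
            raise ValueError(f"pair {p} closes a loop smaller than 3")
        if i in seen or j in seen:
            raise ValueError(f"base in two pairs at {p}")
        seen.update(p)
        while stack and stack[-1][1] < i:
            stack.pop()
        if stack:
            if not (stack[-1][0] < i and j < stack[-1][1]):
                raise ValueError(f"crossing pairs at {p}")
            parent: tuple[int, int] | None = stack[-1]
        else:
            parent = None
        children.setdefault(parent, []).append(p)
        children.setdefault(p, [])
        stack.append(p)
    for p, kids in children.items():
        if p is not None and len(kids) > 1:
            raise ValueError(f"multi-branch loop under pair {p}")
    return children


def structure_energy(sequence: str, pairs: Iterable[tuple[int, int]]) -> float:
    """Free energy (kcal/mol) of an explicit nested, unbranched structure.

    Validates the structure class and applies the module's energy model
    term by term. The empty structure has energy 0.
    """
    seq = _normalize(sequence)
    plist = sorted(pairs)
    if not plist:
        return 0.0
    children = _children_map(plist)
    for i, j in plist:
        if not _pairable(seq, i, j):
            raise ValueError(f"({i},{j}) is not a legal pair: {seq[i]}{seq[j]}")
    total = 0
    for i, j in plist:
        kids = children[(i, j)]
        if not kids:
            total += round(100 * hairpin_penalty(j - i - 1))
        else:
            k, l = kids[0]
            if (k, l) == (i + 1, j - 1):
                total += round(
                    100 * STACKING[(seq[i] + seq[j], seq[k] + seq[l])]
                )
            else:
                total += round(100 * interior_penalty(k - i - 1, j - l - 1))
    return total / 100.0


# ---------------------------------------------------------------------------
# minimum-energy folding
# ---------------------------------------------------------------------------

_INF = 10**9
_NPAIR_BITS = 9  # supports sequences up to 255 pairs (510 nt)


def _key(energy_cents: int, npairs: int) -> int:
    # minimize energy first, then maximize pair count
    return (energy_cents << _NPAIR_BITS) - npairs


def fold_hairpin(sequence: str) -> HairpinStructure:
    """Minimum-free-energy nested structure of a candidate precursor.

    Dynamic program over the unbranched-structure class described in the
    module docstring. Deterministic: ties are broken toward the structure
    with more pairs, then toward pairs opening as far 5' as possible with the
    closest closing base. Interior loops are capped at
    ``MAX_INTERIOR_UNPAIRED`` total unpaired bases.

    Intended for sequences of roughly 40–200 nt (candidate precursor
    windows); shorter inputs are accepted, which the validation suite uses
    to compare against exhaustive enumeration.
    """
    seq = _normalize(sequence)
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")

    stack100 = {
        k: round(100 * v) for k, v in STACKING.items()
    }
    # V[(i, j)] = best key for the region i..j given (i, j) paired
    V: dict[tuple[int, int], int] = {}
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if not _pairable(seq, i, j):
                continue
            best = _key(round(100 * hairpin_penalty(j - i - 1)), 1)
            # stacked pair
            inner = V.get((i + 1, j - 1))
            if inner is not None:
                cand = inner + _key(
                    stack100[(seq[i] + seq[j], seq[i + 1] + seq[j - 1])], 1
                )
                if cand < best:
                    best = cand
            # bulge / internal loops
            for k in range(i + 1, j - MIN_HAIRPIN_LOOP):
                u1 = k - i - 1
                if u1 > MAX_INTERIOR_UNPAIRED:
                    break
                lmin = max(k + MIN_HAIRPIN_LOOP + 1,
                           j - 1 - (MAX_INTERIOR_UNPAIRED - u1))
                for l in range(j - 1, lmin - 1, -1):
                    u2 = j - l - 1
                    if u1 + u2 == 0:
                        continue  # handled as stack
                    inner = V.get((k, l))
                    if inner is None:
                        continue
                    cand = inner + _key(
                        round(100 * interior_penalty(u1, u2)), 1
                    )
                    if cand < best:
                        best = cand
            V[(i, j)] = best

    # W[i] = best key over suffix i..n-1 (possibly empty structure, key 0)
    W = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        best = W[i + 1]
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            vij = V.get((i, j))
            if vij is not None:
                cand = vij + W[j + 1]
                if cand < best:
                    best = cand
        W[i] = best

    pairs: list[tuple[int, int]] = []

    def trace_v(i: int, j: int) -> None:
        pairs.append((i, j))
        target = V[(i, j)]
        # hairpin closure?
        if target == _key(round(100 * hairpin_penalty(j - i - 1)), 1):
            return
        inner = V.get((i + 1, j - 1))
        if inner is not None and target == inner + _key(
            stack100[(seq[i] + seq[j], seq[i + 1] + seq[j - 1])], 1
        ):
            trace_v(i + 1, j - 1)
            return
        for k in range(i + 1, j - MIN_HAIRPIN_LOOP):
            u1 = k - i - 1
            if u1 > MAX_INTERIOR_UNPAIRED:
                break
            for l in range(j - 1, k + MIN_HAIRPIN_LOOP, -1):
                u2 = j - l - 1
                if u1 + u2 == 0 or u1 + u2 > MAX_INTERIOR_UNPAIRED:
                    continue
                inner = V.get((k, l))
                if inner is not None and target == inner + _key(
                    round(100 * interior_penalty(u1, u2)), 1
                ):
                    trace_v(k, l)
                    return
        raise AssertionError("traceback failed")  # pragma: no cover

    i = 0
    while i < n:
        # prefer pairing i whenever doing so achieves the optimal key
        # (the key already encodes the more-pairs preference)
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            vij = V.get((i, j))
            if vij is not None and vij + W[j + 1] == W[i]:
                trace_v(i, j)
                i = j + 1
                break
        else:
            if W[i] != W[i + 1]:  # pragma: no cover
                raise AssertionError("traceback failed at exterior level")
            i += 1

    energy = structure_energy(seq, pairs) if pairs else 0.0
    children = _children_map(pairs) if pairs else {None: []}
    n_loops = sum(
        1 for p, kids in children.items() if p is not None and not kids
    )
    return HairpinStructure(
        pairs=frozenset(pairs), energy=energy, n_loops=n_loops, length=n
    )


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------

def check_hairpin_criteria(
    structure: HairpinStructure,
    criteria: HairpinCriteria | None = None,
) -> tuple[bool, list[str]]:
    """Evaluate the precursor gates; returns (pass, violated clauses).

    Clause names: ``energy`` (folding energy not below the threshold),
    ``min_paired`` (fewer paired nucleotides than required), ``loop_count``
    (more terminal loops than allowed).
    """
    crit = criteria or HairpinCriteria()
    reasons = []
    if not structure.energy < crit.mfe_max:
        reasons.append("energy")
    if structure.paired_count < crit.min_paired:
        reasons.append("min_paired")
    if structure.n_loops > crit.max_loops:
        reasons.append("loop_count")
    return (not reasons, reasons)


def _position_classes(structure: HairpinStructure) -> list[str]:
    """Per-position class: P paired, B bulge, I internal loop, H hairpin
    loop, E exterior/unclassified unpaired."""
    cls = ["E"] * structure.length
    pairs = sorted(structure.pairs)
    if not pairs:
        return cls
    children = _children_map(pairs)
    for i, j in pairs:
        cls[i] = cls[j] = "P"
    for p, kids in children.items():
        if p is None:
            continue
        i, j = p
        if not kids:
            for q in range(i + 1, j):
                cls[q] = "H"
        else:
            k, l = kids[0]
            u1, u2 = k - i - 1, j - l - 1
            kind = "B" if (u1 == 0 or u2 == 0) else "I"
            for q in range(i + 1, k):
                cls[q] = kind
            for q in range(l + 1, j):
                cls[q] = kind
    return cls


def evaluate_mature_placement(
    structure: HairpinStructure,
    mature_span: tuple[int, int],
    criteria: MatureCriteria | None = None,
) -> tuple[bool, dict[str, int]]:
    """Check mature-miRNA placement quality within the folded precursor.

    ``mature_span`` is 1-based inclusive on the precursor. Within the span,
    counts bulged nucleotides, mismatched/asymmetrically-unpaired
    nucleotides, and the longest run of consecutive unpaired nucleotides;
    passes when all three are within ``criteria``.
    """
    crit = criteria or MatureCriteria()
    s, e = mature_span
    if s < 1 or e > structure.length or s > e:
        raise ValueError(f"mature span {mature_span} outside precursor")
    cls = _position_classes(structure)[s - 1 : e]
    bulged = sum(1 for c in cls if c == "B")
    mismatch = sum(1 for c in cls if c in "IHE")
    run = best = 0
    for c in cls:
        run = run + 1 if c != "P" else 0
        best = max(best, run)
    stats = {
        "bulged": bulged,
        "mismatch_or_asym": mismatch,
        "max_continuous": best,
    }
    ok = (
        bulged <= crit.max_bulged
        and mismatch <= crit.max_mismatch_or_asym
        and best <= crit.max_continuous_mismatch
    )
    return ok, stats


def check_duplex_overhang(
    structure: HairpinStructure,
    mature5p_span: tuple[int, int],
    mature3p_span: tuple[int, int],
    tolerance: int = 1,
) -> tuple[bool, dict[str, int | None]]:
    """Check for the ~2-nt 3' overhangs of a Dicer/Drosha duplex.

    Spans are 1-based inclusive. For each arm, the overhang is the number of
    bases its partner arm's 3' end extends beyond the pairing partner of this
    arm's 5' end (adjusted for leading unpaired bases). Passes when both
    overhangs are within ``tolerance`` of 2.
    """
    s5, e5 = mature5p_span
    s3, e3 = mature3p_span
    if e5 >= s3:
        raise ValueError("mature arms overlap")
    partner = structure.partner_map()

    def overhang(anchor_start: int, anchor_end: int, other_end: int):
        for p in range(anchor_start, anchor_end + 1):
            j = partner.get(p - 1)
            if j is not None:
                return (other_end - (j + 1)) - (p - anchor_start)
        return None

    o3 = overhang(s5, e5, e3)  # 3' overhang of the 3p arm
    o5 = overhang(s3, e3, e5)  # 3' overhang of the 5p arm
    detail = {"overhang_3p": o3, "overhang_5p": o5}
    ok = (
        o3 is not None
        and o5 is not None
        and abs(o3 - 2) <= tolerance
        and abs(o5 - 2) <= tolerance
    )
    return ok, detail


# ---------------------------------------------------------------------------
# dot-bracket
# ---------------------------------------------------------------------------

def to_dot_bracket(structure: HairpinStructure) -> str:
    out = ["."] * structure.length
    for i, j in structure.pairs:
        out[i] = "("
        out[j] = ")"
    return "".join(out)


def from_dot_bracket(sequence: str, db: str) -> HairpinStructure:
    """Build a structure from a dot-bracket string (energy recomputed)."""
    if len(db) != len(sequence):
        raise ValueError("dot-bracket length mismatch")
    stack: list[int] = []
    pairs = []
    for idx, c in enumerate(db):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            pairs.append((stack.pop(), idx))
        elif c != ".":
            raise ValueError(f"bad dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket")
    energy = structure_energy(sequence, pairs)
    children = _children_map(sorted(pairs)) if pairs else {None: []}
    n_loops = sum(
        1 for p, kids in children.items() if p is not None and not kids
    )
    return HairpinStructure(
        pairs=frozenset(pairs),
        energy=energy,
        n_loops=n_loops,
        length=len(sequence),
    )
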