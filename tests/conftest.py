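"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by brute force (exhaustive
enumeration, sliding-window scans, direct tail summation) so the optimized
implementations are checked against independent computations.
"""

from __future__ import annotations

import math
import random

import pytest

from miredit.hairpin_fold import (
    MIN_HAIRPIN_LOOP,
    _PAIRABLE,
    structure_energy,
)
from miredit.synthetic_data import (
    EditingEvent,
    SimulationConfig,
    SnpEvent,
    TailEvent,
    build_genome,
    simulate_profile,
)


# ---------------------------------------------------------------------------
# folding oracle: explicit enumeration of every nested unbranched structure
# ---------------------------------------------------------------------------

def enumerate_structures(seq: str):
    """Yield every nested structure (tuples of 0-based pairs) in which each
    pair encloses at most one directly-nested pair."""
    n = len(seq)

    def pairable(i, j):
        return seq[i] + seq[j] in _PAIRABLE

    def helix_chains(i, j):
        chains = [((i, j),)]
        for k in range(i + 1, j):
            for l in range(j - 1, k + MIN_HAIRPIN_LOOP, -1):
                if (k, l) != (i, j) and pairable(k, l):
                    for inner in helix_chains(k, l):
                        chains.append(((i, j),) + inner)
        return chains

    def forests(i, j):
        if i >= j:
            yield ()
            return
        yield from forests(i + 1, j)
        for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            if pairable(i, k):
                for chain in helix_chains(i, k):
                    for rest in forests(k + 1, j):
                        yield chain + rest

    yield from forests(0, n - 1)


def brute_force_mfe(seq: str) -> float:
    """Minimum energy over all enumerated structures (0 for the empty one)."""
    best = 0.0
    for s in enumerate_structures(seq):
        if s:
            e = structure_energy(seq, s)
            if e < best:
                best = e
    return best


# ---------------------------------------------------------------------------
# binomial tail oracle: direct summation
# ---------------------------------------------------------------------------

def binomial_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), summed term by term."""
    if k <= 0:
        return 1.0
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


# ---------------------------------------------------------------------------
# sliding-window precursor alignment oracle
# ---------------------------------------------------------------------------

def brute_force_align(read: str, prec: str, max_tail: int = 3, max_mm: int = 1):
    """All (offset, mismatches, soft_tail) placements by plain scanning."""
    out = []
    L = len(read)
    for start0 in range(len(prec)):
        overhang = max(0, start0 + L - len(prec))
        if overhang > max_tail:
            continue
        tail = overhang
        while (
            tail < max_tail
            and tail < L
            and read[L - tail - 1] != prec[start0 + L - tail - 1]
        ):
            tail += 1
        templated = L - tail
        if templated < 1:
            continue
        mm = [
            (start0 + i + 1, prec[start0 + i], read[i])
            for i in range(templated)
            if read[i] != prec[start0 + i]
        ]
        if len(mm) <= max_mm:
            out.append((start0 + 1, tuple(mm), read[templated:]))
    return out


# ---------------------------------------------------------------------------
# canonical small study
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def demo_cfg() -> SimulationConfig:
    return SimulationConfig(
        genome_length=4000,
        n_precursors=4,
        n_decoys=1,
        coverage_per_mature=200,
        editing_events=(
            EditingEvent(0, 6, "A", "G", 0.30),
            EditingEvent(1, 9, "C", "T", 0.10),
        ),
        snp_events=(SnpEvent(2, 10, "G", "A"),),
        tail_events=(TailEvent(3, "AA", 1.0),),
        base_quality=35,
        seed=42,
    )


@pytest.fixture(scope="session")
def demo_study(demo_cfg):
    genome, truth = build_genome(demo_cfg)
    reads = simulate_profile(demo_cfg, truth)
    return genome, truth, reads


@pytest.fixture
def rng():
    return random.Random(1234)
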