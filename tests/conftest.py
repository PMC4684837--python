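"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by routes independent of the
package implementation: global alignment by recursion over monotone edit
paths with explicit gap-open bookkeeping, and the hypergeometric tail by
counting placements of one profile's ones.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
import pytest

from phyloprofiler import NucleotideSequence, SubstitutionScheme
from phyloprofiler.annotation import PredictionEntry, PredictionList
from phyloprofiler.evaluation import GeneEvaluationRecord
from phyloprofiler.go import FunctionRecord

BASES = "ACGT"


def random_sequence(rng: np.random.Generator, length: int, seq_id: str = "seq") -> NucleotideSequence:
    return NucleotideSequence(seq_id, "".join(rng.choice(list(BASES), size=length)))


@pytest.fixture
def small_scheme() -> SubstitutionScheme:
    return SubstitutionScheme(
        match_score=2, transition_score=1, transversion_score=-2,
        gap_open=-5, gap_extend=-2,
    )


# ---------------------------------------------------------------------------
# alignment oracles
# ---------------------------------------------------------------------------

DIAG, UP, LEFT = 0, 1, 2


def nw_oracle(a: str, b: str, scheme: SubstitutionScheme) -> int:
    """Best global score by recursion over monotone edit paths.

    The recursion carries the previous move so gap openings are charged
    explicitly (a gap of length L costs gap_open + (L-1) * gap_extend, and
    switching between insertion and deletion re-opens). States are memoised;
    the same recursion without memoisation is `nw_path_enumeration`.
    """
    S = scheme.matrix()
    enc = {c: i for i, c in enumerate("ACGTN")}
    qa = [enc[c] for c in a]
    qb = [enc[c] for c in b]
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: int) -> int:
        if i == n and j == m:
            return 0
        best = -(10**15)
        if i < n and j < m:
            best = max(best, int(S[qa[i], qb[j]]) + rec(i + 1, j + 1, DIAG))
        if i < n:
            cost = scheme.gap_extend if prev == UP else scheme.gap_open
            best = max(best, cost + rec(i + 1, j, UP))
        if j < m:
            cost = scheme.gap_extend if prev == LEFT else scheme.gap_open
            best = max(best, cost + rec(i, j + 1, LEFT))
        return best

    return rec(0, 0, DIAG)


def nw_path_enumeration(a: str, b: str, scheme: SubstitutionScheme) -> int:
    """Literal enumeration of every monotone edit path (tiny inputs only)."""
    S = scheme.matrix()
    enc = {c: i for i, c in enumerate("ACGTN")}
    qa = [enc[c] for c in a]
    qb = [enc[c] for c in b]
    n, m = len(a), len(b)
    best = [-(10**15)]

    def walk(i: int, j: int, prev: int, score: int) -> None:
        if i == n and j == m:
            best[0] = max(best[0], score)
            return
        if i < n and j < m:
            walk(i + 1, j + 1, DIAG, score + int(S[qa[i], qb[j]]))
        if i < n:
            cost = scheme.gap_extend if prev == UP else scheme.gap_open
            walk(i + 1, j, UP, score + cost)
        if j < m:
            cost = scheme.gap_extend if prev == LEFT else scheme.gap_open
            walk(i, j + 1, LEFT, score + cost)

    walk(0, 0, DIAG, 0)
    return best[0]


@pytest.fixture
def alignment_oracle():
    return nw_oracle


# ---------------------------------------------------------------------------
# hypergeometric oracle
# ---------------------------------------------------------------------------


def hypergeom_tail_by_enumeration(N: int, n1: int, n2: int, n12: int) -> float:
    """P(overlap >= n12) by counting all C(N, n2) placements of the second
    profile's ones against a fixed set of n1 positions."""
    first = set(range(n1))
    hits = 0
    total = 0
    for combo in itertools.combinations(range(N), n2):
        total += 1
        if len(first.intersection(combo)) >= n12:
            hits += 1
    return hits / total if total else 1.0


def hypergeom_overlap_histogram(N: int, n1: int, n2: int) -> np.ndarray:
    """Counts of placements of n2 ones by overlap with the first n1 positions."""
    first = set(range(n1))
    hist = np.zeros(min(n1, n2) + 1, dtype=np.int64)
    for combo in itertools.combinations(range(N), n2):
        hist[len(first.intersection(combo))] += 1
    return hist


@pytest.fixture
def hypergeom_oracle():
    return hypergeom_tail_by_enumeration


# ---------------------------------------------------------------------------
# hand-built evaluation cohort
# ---------------------------------------------------------------------------


def term(n: int, domain: str = "F") -> tuple[str, str]:
    return (f"GO:{n:07d}", domain)


def prediction(gene_id: str, entry_specs) -> PredictionList:
    entries = tuple(
        PredictionEntry(terms=frozenset(terms), P=p, n12=5, supporting_genes=("s",))
        for terms, p in entry_specs
    )
    return PredictionList(gene_id, entries)


def hand_cohort():
    """Ten hand-built genes with hand-enumerated C0..C7 membership.

    Returns (records, expected perfect-match counts, expected fuzzy-match
    counts) for k_top = 5 and the molecular-function domain.
    """
    A, B, C, D, E, F2, G, H = (term(i) for i in range(1, 9))
    X, Y, Z, W, V = (term(i) for i in range(101, 106))

    def known(gene_id, *terms):
        return FunctionRecord(gene_id, frozenset(terms))

    records = [
        # known {A}, top-1 {A}: C6 under both modes
        GeneEvaluationRecord("g01", known("g01", A), prediction("g01", [({A}, 1e-9)])),
        # known {A,B} found exactly at rank 3: C6
        GeneEvaluationRecord(
            "g02",
            known("g02", A, B),
            prediction("g02", [({X}, 1e-9), ({Y}, 1e-8), ({A, B}, 1e-7)]),
        ),
        # known {C} appears only at rank 6 (> k_top): C7
        GeneEvaluationRecord(
            "g03",
            known("g03", C),
            prediction(
                "g03",
                [({X}, 1e-9), ({Y}, 2e-9), ({Z}, 3e-9), ({W}, 4e-9), ({V}, 5e-9), ({C}, 6e-9)],
            ),
        ),
        # known but no predictions: C4
        GeneEvaluationRecord("g04", known("g04", D), None),
        # predictions only: C3
        GeneEvaluationRecord("g05", None, prediction("g05", [({X}, 1e-9)])),
        # neither known nor predicted
        GeneEvaluationRecord("g06", None, None),
        # superset prediction {E,F2} vs known {E}: fuzzy C6, perfect C7
        GeneEvaluationRecord(
            "g07", known("g07", E), prediction("g07", [({E, F2}, 1e-9)])
        ),
        GeneEvaluationRecord("g08", known("g08", G), prediction("g08", [({G}, 1e-9)])),
        GeneEvaluationRecord("g09", None, prediction("g09", [({Y}, 1e-9)])),
        # known {H} at rank 2
        GeneEvaluationRecord(
            "g10", known("g10", H), prediction("g10", [({X}, 1e-9), ({H}, 1e-8)])
        ),
    ]
    perfect = {"C0": 10, "C1": 7, "C2": 8, "C3": 2, "C4": 1, "C5": 6, "C6": 4, "C7": 2}
    fuzzy = {"C0": 10, "C1": 7, "C2": 8, "C3": 2, "C4": 1, "C5": 6, "C6": 5, "C7": 1}
    return records, perfect, fuzzy


@pytest.fixture
def evaluation_cohort():
    return hand_cohort()
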