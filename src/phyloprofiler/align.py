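"""Global alignment, candidate-region search and Monte-Carlo significance.

Homology between a gene and a genome is established in three steps:

1. a fast seed-and-extend local search (exact k-mer seeds, ungapped X-drop
   extension under several (reward, penalty) settings, both strands) proposes
   candidate regions;
2. each candidate is extended to a gene-length genome window and scored with
   an end-to-end (Needleman-Wunsch) global alignment under the
   purine/pyrimidine scheme;
3. the score F is standardised against a Monte-Carlo null built by aligning
   composition-preserving shuffles of the gene against the same window:
   Z = (F - M(F)) / sqrt(D(F)), with M and D the sample mean and sample
   variance of the shuffled scores.

Large Z means the alignment score is far above what the gene's base
composition alone produces, i.e. genuine sequence homology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numba
import numpy as np

from .config import as_rng
from .sequences import DEFAULT_SCHEME, NucleotideSequence, SubstitutionScheme

__all__ = [
    "AlignmentSignificance",
    "CandidateRegion",
    "DegenerateNullError",
    "DEFAULT_SWEEP",
    "extend_to_global",
    "find_candidate_regions",
    "global_alignment_score",
    "monte_carlo_significance",
    "shuffle_preserving_triplet_periodicity",
    "shuffle_sequence",
    "z_score",
]

DEFAULT_SWEEP: tuple[tuple[int, int], ...] = ((1, -2), (1, -3), (2, -3))


class DegenerateNullError(ValueError):
    """The shuffled-score null had zero variance; Z is undefined."""


@numba.njit(nogil=True, cache=False)
def _nw_score(q, t, S, gap_open, gap_extend):  # pragma: no cover - jitted
    n = q.shape[0]
    m = t.shape[0]
    NEG = -(10**15)
    Mp = np.empty(m + 1, np.int64)
    Xp = np.empty(m + 1, np.int64)
    Yp = np.empty(m + 1, np.int64)
    Mc = np.empty(m + 1, np.int64)
    Xc = np.empty(m + 1, np.int64)
    Yc = np.empty(m + 1, np.int64)
    Mp[0] = 0
    Xp[0] = NEG
    Yp[0] = NEG
    for j in range(1, m + 1):
        Mp[j] = NEG
        Xp[j] = NEG
        Yp[j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        Mc[0] = NEG
        Xc[0] = gap_open + (i - 1) * gap_extend
        Yc[0] = NEG
        for j in range(1, m + 1):
            s = S[q[i - 1], t[j - 1]]
            best = Mp[j - 1]
            if Xp[j - 1] > best:
                best = Xp[j - 1]
            if Yp[j - 1] > best:
                best = Yp[j - 1]
            Mc[j] = best + s
            x = Mp[j] + gap_open
            if Xp[j] + gap_extend > x:
                x = Xp[j] + gap_extend
            if Yp[j] + gap_open > x:
                x = Yp[j] + gap_open
            Xc[j] = x
            y = Mc[j - 1] + gap_open
            if Yc[j - 1] + gap_extend > y:
                y = Yc[j - 1] + gap_extend
            if Xc[j - 1] + gap_open > y:
                y = Xc[j - 1] + gap_open
            Yc[j] = y
        Mp, Mc = Mc, Mp
        Xp, Xc = Xc, Xp
        Yp, Yc = Yc, Yp
    best = Mp[m]
    if Xp[m] > best:
        best = Xp[m]
    if Yp[m] > best:
        best = Yp[m]
    return best


def global_alignment_score(
    query: NucleotideSequence,
    target: NucleotideSequence,
    scheme: SubstitutionScheme = DEFAULT_SCHEME,
) -> int:
    """Optimal end-to-end global alignment score (Gotoh affine-gap recursion).

    Symmetric in its two arguments. Both sequences must be non-empty; a gap of
    length L costs ``gap_open + (L - 1) * gap_extend`` and terminal gaps are
    penalised like internal ones.
    """
    if len(query) == 0 or len(target) == 0:
        raise ValueError("global alignment requires two non-empty sequences")
    return int(
        _nw_score(
            query.encoded(),
            target.encoded(),
            scheme.matrix(),
            scheme.gap_open,
            scheme.gap_extend,
        )
    )


# ---------------------------------------------------------------------------
# candidate-region search (seed and extend)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateRegion:
    """A genome span where local search found gene-like similarity.

    Coordinates are 0-based half-open on the forward strand of the genome;
    ``strand`` records which strand the similarity lies on. ``seed_score`` is
    the best ungapped extension score that produced the region.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    seed_score: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("region must satisfy 0 <= start < end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


def _ungapped_extend(
    q: str, t: str, qpos: int, tpos: int, k: int, reward: int, penalty: int, xdrop: int
) -> tuple[int, int, int]:
    """X-drop ungapped extension of an exact k-mer seed.

    Returns (score, left, right): the best segment spans
    t[tpos - left : tpos + k + right] against the same-length query span.
    """
    score = k * reward
    best_r = 0
    run = 0
    i = 0
    n_r = min(len(q) - (qpos + k), len(t) - (tpos + k))
    best_run = 0
    while i < n_r:
        run += reward if q[qpos + k + i] == t[tpos + k + i] else penalty
        i += 1
        if run > best_run:
            best_run = run
            best_r = i
        if run < best_run - xdrop:
            break
    best_l = 0
    run = 0
    best_run_l = 0
    i = 0
    n_l = min(qpos, tpos)
    while i < n_l:
        run += reward if q[qpos - 1 - i] == t[tpos - 1 - i] else penalty
        i += 1
        if run > best_run_l:
            best_run_l = run
            best_l = i
        if run < best_run_l - xdrop:
            break
    return score + best_run + best_run_l, best_l, best_r


def _search_strand(
    query: NucleotideSequence,
    target: str,
    sweep: Sequence[tuple[int, int]],
    k: int,
    min_score: int,
    xdrop: int,
) -> list[tuple[int, int, float]]:
    """Seed-and-extend search of one strand; returns (start, end, score) on target."""
    q = query.residues
    if len(q) < k or len(target) < k:
        return []
    kmers: dict[str, list[int]] = {}
    for i in range(len(q) - k + 1):
        kmers.setdefault(q[i : i + k], []).append(i)
    # per-diagonal high-water mark so overlapping seeds on one diagonal are
    # extended only once
    covered: dict[int, int] = {}
    segments: list[tuple[int, int, float]] = []
    for tpos in range(len(target) - k + 1):
        hits = kmers.get(target[tpos : tpos + k])
        if not hits:
            continue
        for qpos in hits:
            diag = tpos - qpos
            if covered.get(diag, -1) >= tpos:
                continue
            best = None
            reach = tpos + k - 1
            for reward, penalty in sweep:
                sc, left, right = _ungapped_extend(
                    q, target, qpos, tpos, k, reward, penalty, xdrop
                )
                reach = max(reach, tpos + k + right - 1)
                if sc >= min_score and (best is None or sc > best[0]):
                    best = (sc, left, right)
            covered[diag] = max(covered.get(diag, -1), reach)
            if best is not None:
                sc, left, right = best
                segments.append((tpos - left, tpos + k + right, float(sc)))
    return segments


def _merge_segments(
    segments: list[tuple[int, int, float]],
) -> list[tuple[int, int, float]]:
    if not segments:
        return []
    segments.sort()
    merged = [list(segments[0])]
    for s, e, sc in segments[1:]:
        if s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = max(merged[-1][2], sc)
        else:
            merged.append([s, e, sc])
    return [(int(s), int(e), float(sc)) for s, e, sc in merged]


def find_candidate_regions(
    query: NucleotideSequence,
    genome: NucleotideSequence,
    sweep: Sequence[tuple[int, int]] = DEFAULT_SWEEP,
    *,
    k: int = 11,
    min_score: int = 25,
    xdrop: int = 20,
) -> list[CandidateRegion]:
    """Find candidate homologous regions of ``genome`` for ``query``.

    Exact k-mer seeds are extended without gaps under each (reward, penalty)
    setting of ``sweep``; segments reaching ``min_score`` become regions.
    Both strands are searched (the reverse complement of the genome) and
    overlapping regions on the same strand are merged. Coordinates always
    refer to the forward strand of the genome.
    """
    if not sweep:
        raise ValueError("sweep must contain at least one (reward, penalty) setting")
    if len(query) == 0 or len(genome) == 0:
        raise ValueError("query and genome must be non-empty")
    L = len(genome)
    regions: list[CandidateRegion] = []
    for strand in "+-":
        target = genome.residues if strand == "+" else genome.reverse_complement().residues
        segs = _merge_segments(
            _search_strand(query, target, tuple(sweep), k, min_score, xdrop)
        )
        for s, e, sc in segs:
            if strand == "-":
                s, e = L - e, L - s
            regions.append(CandidateRegion(genome.id, s, e, strand, sc))
    regions.sort(key=lambda r: (-r.seed_score, r.start, r.strand))
    return regions


def extend_to_global(
    query: NucleotideSequence,
    genome: NucleotideSequence,
    region: CandidateRegion,
    scheme: SubstitutionScheme = DEFAULT_SCHEME,
) -> tuple[NucleotideSequence, int]:
    """Extend a candidate region to a gene-length window and score it globally.

    The window has exactly the query's length, is centred on the region's
    midpoint (clipped at the genome ends; the whole genome if it is shorter
    than the query) and is reverse-complemented for minus-strand regions, so
    the returned score is a true end-to-end global alignment of the gene
    against the genomic copy's neighbourhood.
    """
    L = len(genome)
    if region.end > L:
        raise ValueError(
            f"region [{region.start}, {region.end}) exceeds genome length {L}"
        )
    qlen = len(query)
    if region.strand == "-":
        s, e = L - region.end, L - region.start
        frame = genome.reverse_complement().residues
    else:
        s, e = region.start, region.end
        frame = genome.residues
    center = (s + e) // 2
    start = center - qlen // 2
    start = max(0, min(start, L - qlen))
    if L <= qlen:
        start, stop = 0, L
    else:
        stop = start + qlen
    window = NucleotideSequence(
        f"{genome.id}:{start}-{stop}({region.strand})", frame[start:stop]
    )
    return window, global_alignment_score(query, window, scheme)


# ---------------------------------------------------------------------------
# shuffles and Monte-Carlo significance
# ---------------------------------------------------------------------------


def shuffle_sequence(
    seq: NucleotideSequence, rng: int | np.random.Generator | None = None
) -> NucleotideSequence:
    """Uniform random permutation of the residues (base composition preserved)."""
    gen = as_rng(rng)
    arr = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    shuffled = arr[gen.permutation(arr.size)]
    return NucleotideSequence(seq.id, shuffled.tobytes().decode("ascii"), seq.description)


def shuffle_preserving_triplet_periodicity(
    seq: NucleotideSequence, rng: int | np.random.Generator | None = None
) -> NucleotideSequence:
    """Shuffle within codon-position classes (positions 0, 1, 2 mod 3).

    Bases are permuted separately within each codon-position class over the
    complete codons, preserving the per-codon-position base composition that
    carries the triplet periodicity of coding sequences. Trailing bases of an
    incomplete final codon stay in place.
    """
    gen = as_rng(rng)
    arr = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8).copy()
    n_full = 3 * (arr.size // 3)
    for offset in range(3):
        idx = np.arange(offset, n_full, 3)
        if idx.size > 1:
            arr[idx] = arr[idx[gen.permutation(idx.size)]]
    return NucleotideSequence(seq.id, arr.tobytes().decode("ascii"), seq.description)


def z_score(F: float, M: float, D: float) -> float:
    """Standardised alignment score (F - M) / sqrt(D); D is a variance."""
    if D <= 0:
        raise DegenerateNullError(
            f"shuffled-score variance D={D} is not positive; Z undefined"
        )
    return (F - M) / math.sqrt(D)


@dataclass(frozen=True)
class AlignmentSignificance:
    """Global alignment score with its Monte-Carlo shuffle null.

    ``M`` and ``D`` are the sample mean and unbiased sample variance of the
    global scores of ``n_shuffles`` composition-preserving shuffles of the
    query against the same window; ``Z = (F - M) / sqrt(D)``.
    """

    F: float
    M: float
    D: float
    Z: float
    n_shuffles: int


def monte_carlo_significance(
    query: NucleotideSequence,
    window: NucleotideSequence,
    scheme: SubstitutionScheme = DEFAULT_SCHEME,
    n_shuffles: int = 1000,
    rng: int | np.random.Generator | None = None,
) -> AlignmentSignificance:
    """Monte-Carlo standardised significance of a global alignment.

    Aligns the real query and ``n_shuffles`` random permutations of it against
    ``window``; the shuffled scores form the null sample from which the mean M
    and unbiased variance D (divisor n-1) are taken.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2 to estimate a sample variance")
    gen = as_rng(rng)
    S = scheme.matrix()
    q = query.encoded()
    w = window.encoded()
    if q.size == 0 or w.size == 0:
        raise ValueError("query and window must be non-empty")
    F = float(_nw_score(q, w, S, scheme.gap_open, scheme.gap_extend))
    scores = np.empty(n_shuffles, dtype=np.float64)
    for i in range(n_shuffles):
        perm = q[gen.permutation(q.size)]
        scores[i] = _nw_score(perm, w, S, scheme.gap_open, scheme.gap_extend)
    M = float(scores.mean())
    D = float(scores.var(ddof=1))
    return AlignmentSignificance(F=F, M=M, D=D, Z=z_score(F, M, D), n_shuffles=n_shuffles)
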