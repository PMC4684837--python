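"""Profile comparison by exact hypergeometric co-occurrence and function prediction.

Two phylogenetic profiles over the same N-genome panel are compared through
the number of panel genomes in which both genes occur. Under the null that
the n2 occurrences of the second gene fall on panel positions independently
of the first gene's n1 occurrences, the number of shared positions follows
the hypergeometric distribution; the similarity measure is the exact upper
tail

    P(X >= n12) = sum_{k=n12}^{min(n1,n2)} C(n1,k) C(N-n1, n2-k) / C(N, n2),

computed in log space so that values far below 1e-100 keep their ordering.
Genes whose database profiles reach P <= P0 contribute their GO-term sets to
the prediction list of the query, sorted ascending by P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

from .go import FunctionRecord, TaggedTerm, parse_terms, serialize_terms

if TYPE_CHECKING:  # pragma: no cover
    from .profiles import PhylogeneticProfile, ProfileDatabase

__all__ = [
    "PredictionEntry",
    "PredictionList",
    "ProfileComparison",
    "Thresholds",
    "compare_profiles",
    "find_similar_profiles",
    "hypergeometric_p",
    "predict_functions",
    "read_predictions_tsv",
    "write_predictions_tsv",
]

P_FLOOR = 1e-300


@dataclass(frozen=True)
class Thresholds:
    """Operating point of the annotation method.

    p0 : profile-similarity cutoff; pairs with P > p0 are considered
        unrelated (the published value, 1e-7, is calibrated for a panel of
        ~1200 genomes).
    k_top : depth of the prediction list used when judging agreement with a
        known function.
    z_min : alignment-significance cutoff used upstream when profiles are
        built.
    """

    p0: float = 1e-7
    k_top: int = 5
    z_min: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.p0 < 1):
            raise ValueError("p0 must lie in (0, 1)")
        if self.k_top < 1:
            raise ValueError("k_top must be >= 1")


def hypergeometric_p(N: int, n1: int, n2: int, n12: int) -> float:
    """Exact upper-tail hypergeometric probability of >= n12 co-occurrences.

    Computed with log-gamma arithmetic; results below 1e-300 are clamped to
    1e-300 (ordering among clamped values is lost but all lie far below any
    useful threshold).
    """
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ValueError(f"need 0 <= n1, n2 <= N; got N={N}, n1={n1}, n2={n2}")
    if not (0 <= n12 <= min(n1, n2)):
        raise ValueError(f"need 0 <= n12 <= min(n1, n2); got n12={n12}")
    lower = max(0, n1 + n2 - N)
    if n12 <= lower:
        return 1.0
    if n2 < n1:  # the tail is symmetric in (n1, n2); canonicalise for bit-exactness
        n1, n2 = n2, n1
    kmax = min(n1, n2)
    lg = math.lgamma
    # log pmf at the first tail term; subsequent terms follow the exact pmf
    # ratio recurrence pmf(k+1)/pmf(k) = (n1-k)(n2-k) / ((k+1)(N-n1-n2+k+1))
    cur = (
        lg(n1 + 1)
        - lg(n12 + 1)
        - lg(n1 - n12 + 1)
        + lg(N - n1 + 1)
        - lg(n2 - n12 + 1)
        - lg(N - n1 - n2 + n12 + 1)
        - (lg(N + 1) - lg(n2 + 1) - lg(N - n2 + 1))
    )
    logs = [cur]
    for k in range(n12, kmax):
        cur += math.log((n1 - k) * (n2 - k) / ((k + 1) * (N - n1 - n2 + k + 1)))
        logs.append(cur)
    m = max(logs)
    p = math.exp(m) * math.fsum(math.exp(v - m) for v in logs)
    return min(1.0, max(p, P_FLOOR))


@dataclass(frozen=True)
class ProfileComparison:
    """Co-occurrence counts and hypergeometric P for one profile pair."""

    gene_id_1: str
    gene_id_2: str
    N: int
    n1: int
    n2: int
    n12: int
    P: float

    @property
    def clamped(self) -> bool:
        """True when P hit the 1e-300 underflow floor."""
        return self.P <= P_FLOOR


def compare_profiles(
    p: "PhylogeneticProfile", q: "PhylogeneticProfile"
) -> ProfileComparison:
    """Count co-occurrences of two equal-length profiles and compute P."""
    if len(p.bits) != len(q.bits):
        raise ValueError(
            f"panel mismatch: profiles have lengths {len(p.bits)} and {len(q.bits)}"
        )
    n1 = int(p.n_ones)
    n2 = int(q.n_ones)
    n12 = int(np.count_nonzero(p.bits & q.bits))
    return ProfileComparison(
        gene_id_1=p.gene_id,
        gene_id_2=q.gene_id,
        N=len(p.bits),
        n1=n1,
        n2=n2,
        n12=n12,
        P=hypergeometric_p(len(p.bits), n1, n2, n12),
    )


def find_similar_profiles(
    query: "PhylogeneticProfile",
    db: "ProfileDatabase",
    thresholds: Thresholds = Thresholds(),
    *,
    exclude_gene_ids: Iterable[str] = (),
) -> list[ProfileComparison]:
    """All database profiles with P <= p0, sorted ascending by P.

    Ties at equal P are broken by larger n12, then lexicographic gene id.
    ``exclude_gene_ids`` supports leave-own-gene-out evaluation.
    """
    if len(query.bits) != db.panel.N:
        raise ValueError(
            f"panel mismatch: query length {len(query.bits)} vs panel size {db.panel.N}"
        )
    excluded = set(exclude_gene_ids)
    hits = []
    for gene_id, profile in db.profiles.items():
        if gene_id in excluded:
            continue
        cmp_ = compare_profiles(query, profile)
        if cmp_.P <= thresholds.p0:
            hits.append(cmp_)
    hits.sort(key=lambda c: (c.P, -c.n12, c.gene_id_2))
    return hits


@dataclass(frozen=True)
class PredictionEntry:
    """One candidate function: a GO-term set with its best supporting P."""

    terms: frozenset[TaggedTerm]
    P: float
    n12: int
    supporting_genes: tuple[str, ...]


@dataclass(frozen=True)
class PredictionList:
    """Ranked candidate functions for one query gene (ascending P)."""

    query_gene_id: str
    entries: tuple[PredictionEntry, ...] = ()
    reason: str | None = None

    def __post_init__(self) -> None:
        ps = [e.P for e in self.entries]
        if any(b < a for a, b in zip(ps, ps[1:])):
            raise ValueError("prediction entries must be sorted ascending by P")

    def __len__(self) -> int:
        return len(self.entries)

    def top(self, k: int) -> tuple[PredictionEntry, ...]:
        return self.entries[:k]


def predict_functions(
    query: "PhylogeneticProfile",
    db: "ProfileDatabase",
    thresholds: Thresholds = Thresholds(),
    *,
    exclude_gene_ids: Iterable[str] = (),
) -> PredictionList:
    """Ranked GO-term-set predictions for a query profile.

    Database genes passing the p0 cutoff vote with their full term sets;
    genes carrying the same term set are merged into one entry that keeps the
    smallest P and lists every supporting gene. A query profile with fewer
    than two ones cannot reach any realistic p0 and is reported as
    unannotatable ("profile too sparse").
    """
    if query.n_ones < 2:
        return PredictionList(query.gene_id, (), reason="profile too sparse")
    matches = find_similar_profiles(
        query, db, thresholds, exclude_gene_ids=exclude_gene_ids
    )
    by_terms: dict[frozenset[TaggedTerm], list[ProfileComparison]] = {}
    order: list[frozenset[TaggedTerm]] = []
    for cmp_ in matches:
        terms = db.functions[cmp_.gene_id_2].terms
        if terms not in by_terms:
            by_terms[terms] = []
            order.append(terms)
        by_terms[terms].append(cmp_)
    entries = []
    for terms in order:
        group = by_terms[terms]
        best = group[0]  # matches are already sorted ascending by P
        entries.append(
            PredictionEntry(
                terms=terms,
                P=best.P,
                n12=best.n12,
                supporting_genes=tuple(c.gene_id_2 for c in group),
            )
        )
    entries.sort(key=lambda e: (e.P, -e.n12, serialize_terms(e.terms)))
    return PredictionList(query.gene_id, tuple(entries))


def write_predictions_tsv(
    predictions: Iterable[PredictionList], path: str | Path
) -> None:
    """Write ranked predictions: gene_id, rank, P, n12, terms, supporting genes."""
    with open(path, "w") as fh:
        fh.write("gene_id\trank\tP\tn12\tterms\tsupporting_genes\n")
        for pred in predictions:
            if not pred.entries:
                reason = pred.reason or "no profile matches"
                fh.write(f"{pred.query_gene_id}\t0\t\t\t\t# {reason}\n")
                continue
            for rank, entry in enumerate(pred.entries, start=1):
                fh.write(
                    f"{pred.query_gene_id}\t{rank}\t{entry.P:.6e}\t{entry.n12}\t"
                    f"{serialize_terms(entry.terms)}\t"
                    f"{';'.join(entry.supporting_genes)}\n"
                )


def read_predictions_tsv(path: str | Path) -> dict[str, PredictionList]:
    """Read a predictions TSV back into PredictionList objects."""
    rows: dict[str, list[PredictionEntry]] = {}
    reasons: dict[str, str | None] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene_id, rank, p, n12, terms, support = line.split("\t")
            rows.setdefault(gene_id, [])
            if rank == "0":
                reasons[gene_id] = support.lstrip("# ") or None
                continue
            rows[gene_id].append(
                PredictionEntry(
                    terms=parse_terms(terms),
                    P=float(p),
                    n12=int(n12),
                    supporting_genes=tuple(filter(None, support.split(";"))),
                )
            )
    return {
        gene_id: PredictionList(
            gene_id, tuple(entries), reason=reasons.get(gene_id)
        )
        for gene_id, entries in rows.items()
    }
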