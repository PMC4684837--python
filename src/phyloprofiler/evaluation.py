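"""Evaluation of predicted functions against previously known annotations.

Genes are partitioned by the presence of known and predicted functions:

    C0  all genes under study
    C1  genes with a known function
    C2  genes with at least one predicted function
    C3 = C2 - C1   newly annotated genes
    C4 = C1 - C2   known but unannotatable genes
    C5 = C1 & C2   genes with both
    C6  genes of C5 whose known function matches one of the top-K predictions
    C7 = C5 - C6

Two notions of agreement between GO-term sets are supported: *perfect match*
(set equality) and *fuzzy match* (non-empty intersection), optionally
restricted to one GO domain (the molecular-function domain F by default).
Pathway coverage asks how much of a gene's metabolic pathway is recovered by
its top-Q and top-2Q predicted functions, where Q is the number of distinct
functions in the pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import PredictionList
from .go import FunctionRecord, TaggedTerm, filter_terms

__all__ = [
    "EvaluationReport",
    "GeneEvaluationRecord",
    "Pathway",
    "SUBSET_NAMES",
    "assign_pathways",
    "classify_genes",
    "match_fuzzy",
    "match_perfect",
    "pathway_coverage",
    "rank_distribution",
    "read_pathways_tsv",
    "write_pathways_tsv",
]

SUBSET_NAMES = tuple(f"C{i}" for i in range(8))
Q_BINS: tuple[tuple[int, int], ...] = ((1, 4), (5, 9), (10, 14), (15, 19), (20, 24), (25, 30))
MAX_PATHWAY_GENES = 30


def match_perfect(
    a: Iterable[TaggedTerm], b: Iterable[TaggedTerm], domain: str | None = "F"
) -> bool:
    """True iff the (domain-filtered) term sets are equal and non-empty."""
    fa, fb = filter_terms(a, domain), filter_terms(b, domain)
    return bool(fa) and fa == fb


def match_fuzzy(
    a: Iterable[TaggedTerm], b: Iterable[TaggedTerm], domain: str | None = "F"
) -> bool:
    """True iff the (domain-filtered) term sets share at least one term."""
    return bool(filter_terms(a, domain) & filter_terms(b, domain))


_MATCHERS = {"perfect": match_perfect, "fuzzy": match_fuzzy}


@dataclass
class GeneEvaluationRecord:
    """One gene's known function, predictions, and assigned C-subsets."""

    gene_id: str
    known: FunctionRecord | None = None
    predicted: PredictionList | None = None
    subsets: frozenset[str] = frozenset()


@dataclass
class EvaluationReport:
    """Subset counts N0..N7 with shares relative to N0."""

    counts: dict[str, int]
    mode: str
    domain: str | None
    k_top: int
    records: list[GeneEvaluationRecord] = field(repr=False, default_factory=list)

    def shares(self) -> dict[str, float]:
        n0 = self.counts["C0"]
        return {s: (self.counts[s] / n0 if n0 else 0.0) for s in SUBSET_NAMES}

    def to_frame(self) -> pd.DataFrame:
        shares = self.shares()
        return pd.DataFrame(
            {
                "subset": list(SUBSET_NAMES),
                "count": [self.counts[s] for s in SUBSET_NAMES],
                "share_of_C0": [shares[s] for s in SUBSET_NAMES],
            }
        )


def _known_terms(
    record: GeneEvaluationRecord, domain: str | None
) -> frozenset[TaggedTerm]:
    if record.known is None:
        return frozenset()
    return record.known.filtered(domain)


def _predicted_entries(record: GeneEvaluationRecord, domain: str | None):
    """Prediction entries that carry at least one term in the domain."""
    if record.predicted is None:
        return []
    return [e for e in record.predicted.entries if filter_terms(e.terms, domain)]


def classify_genes(
    records: Sequence[GeneEvaluationRecord],
    k_top: int = 5,
    mode: str = "perfect",
    domain: str | None = "F",
) -> EvaluationReport:
    """Assign every gene to the C0..C7 subsets and count them.

    A gene belongs to C1 when its known function has at least one term in the
    chosen domain, to C2 when at least one predicted entry does, and to C6
    when the known term set matches (under ``mode``) one of the first
    ``k_top`` such entries. Prediction lists must be sorted ascending by P.
    """
    if mode not in _MATCHERS:
        raise ValueError(f"mode must be one of {sorted(_MATCHERS)}")
    matcher = _MATCHERS[mode]
    counts = {s: 0 for s in SUBSET_NAMES}
    for record in records:
        if record.predicted is not None:
            ps = [e.P for e in record.predicted.entries]
            if any(b < a for a, b in zip(ps, ps[1:])):
                raise ValueError(
                    f"predictions for {record.gene_id} are not sorted ascending by P"
                )
        known = _known_terms(record, domain)
        entries = _predicted_entries(record, domain)
        subsets = {"C0"}
        if known:
            subsets.add("C1")
        if entries:
            subsets.add("C2")
        if known and not entries:
            subsets.add("C4")
        if entries and not known:
            subsets.add("C3")
        if known and entries:
            subsets.add("C5")
            if any(matcher(known, e.terms, domain) for e in entries[:k_top]):
                subsets.add("C6")
            else:
                subsets.add("C7")
        record.subsets = frozenset(subsets)
        for s in subsets:
            counts[s] += 1
    return EvaluationReport(
        counts=counts, mode=mode, domain=domain, k_top=k_top, records=list(records)
    )


def rank_distribution(
    records: Sequence[GeneEvaluationRecord],
    mode: str = "perfect",
    domain: str | None = "F",
) -> pd.DataFrame:
    """Where in the prediction list the known function is found (C5 genes).

    For each gene having both known and predicted functions, the minimal
    prefix length of the prediction list containing the known function is
    recorded; percentages are relative to the C5 size, so genes whose known
    function never appears leave the cumulative percentage below 100.
    """
    matcher = _MATCHERS[mode]
    ranks: list[int] = []
    n_c5 = 0
    for record in records:
        known = _known_terms(record, domain)
        entries = _predicted_entries(record, domain)
        if not known or not entries:
            continue
        n_c5 += 1
        for pos, entry in enumerate(entries, start=1):
            if matcher(known, entry.terms, domain):
                ranks.append(pos)
                break
    max_pos = max(ranks, default=0)
    rows = []
    cum = 0.0
    for pos in range(1, max_pos + 1):
        count = ranks.count(pos)
        pct = 100.0 * count / n_c5 if n_c5 else 0.0
        cum += pct
        rows.append(
            {"position": pos, "count": count, "percentage": pct, "cumulative_percentage": cum}
        )
    return pd.DataFrame(rows, columns=["position", "count", "percentage", "cumulative_percentage"])


# ---------------------------------------------------------------------------
# metabolic pathways
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pathway:
    """A metabolic pathway: an identified set of member genes."""

    pathway_id: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("pathway must contain at least one gene")


def read_pathways_tsv(path) -> list[Pathway]:
    """Read pathway membership rows: pathway_id <TAB> gene_id."""
    members: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith("pathway_id"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            members.setdefault(parts[0], set()).add(parts[1])
    return [Pathway(pid, frozenset(genes)) for pid, genes in sorted(members.items())]


def write_pathways_tsv(pathways: Iterable[Pathway], path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway_id\tgene_id\n")
        for pw in sorted(pathways, key=lambda p: p.pathway_id):
            for gene_id in sorted(pw.gene_ids):
                fh.write(f"{pw.pathway_id}\t{gene_id}\n")


def assign_pathways(
    pathways: Sequence[Pathway], max_genes: int = MAX_PATHWAY_GENES
) -> dict[str, Pathway]:
    """Map each gene to its smallest containing pathway.

    Pathways with more than ``max_genes`` genes are dropped; genes in no
    remaining pathway are absent from the mapping. Ties in pathway size are
    broken by lexicographic pathway id.
    """
    kept = [p for p in pathways if len(p.gene_ids) <= max_genes]
    assignment: dict[str, Pathway] = {}
    for pw in sorted(kept, key=lambda p: (len(p.gene_ids), p.pathway_id)):
        for gene_id in pw.gene_ids:
            assignment.setdefault(gene_id, pw)
    return assignment


def _pathway_functions(
    pathway: Pathway,
    functions: Mapping[str, FunctionRecord],
    domain: str | None,
) -> list[frozenset[TaggedTerm]]:
    """Distinct (domain-filtered, non-empty) member term sets; Q = their count."""
    seen: list[frozenset[TaggedTerm]] = []
    for gene_id in sorted(pathway.gene_ids):
        record = functions.get(gene_id)
        if record is None:
            continue
        terms = record.filtered(domain)
        if terms and terms not in seen:
            seen.append(terms)
    return seen


def pathway_coverage(
    predictions: Mapping[str, PredictionList],
    assignment: Mapping[str, Pathway],
    functions: Mapping[str, FunctionRecord],
    mode: str = "perfect",
    domain: str | None = "F",
    bins: Sequence[tuple[int, int]] = Q_BINS,
) -> pd.DataFrame:
    """Average share of pathway functions found in top-Q and top-2Q predictions.

    For each mapped gene with predictions, Q is the number of distinct
    functions of its assigned pathway; the gene's score is the fraction of
    those functions matched (under ``mode``) by some entry of its top-Q
    (resp. top-2Q) prediction list. Scores are averaged within Q-range bins.
    """
    matcher = _MATCHERS[mode]
    rows = []
    for gene_id, pathway in assignment.items():
        pred = predictions.get(gene_id)
        pw_functions = _pathway_functions(pathway, functions, domain)
        q = len(pw_functions)
        if q == 0:
            continue
        shares = {}
        for label, depth in (("top_Q", q), ("top_2Q", 2 * q)):
            if pred is None or not pred.entries:
                shares[label] = 0.0
                continue
            entries = [e for e in pred.entries if filter_terms(e.terms, domain)][:depth]
            hit = sum(
                1
                for fn in pw_functions
                if any(matcher(fn, e.terms, domain) for e in entries)
            )
            shares[label] = hit / q
        rows.append(
            {"gene_id": gene_id, "pathway_id": pathway.pathway_id, "Q": q, **shares}
        )
    per_gene = pd.DataFrame(rows, columns=["gene_id", "pathway_id", "Q", "top_Q", "top_2Q"])
    out = []
    for lo, hi in bins:
        sub = per_gene[(per_gene["Q"] >= lo) & (per_gene["Q"] <= hi)]
        out.append(
            {
                "Q_range": f"{lo}-{hi}",
                "n_genes": len(sub),
                "top_Q": sub["top_Q"].mean() if len(sub) else float("nan"),
                "top_2Q": sub["top_2Q"].mean() if len(sub) else float("nan"),
            }
        )
    table = pd.DataFrame(out)
    table.attrs["per_gene"] = per_gene
    return table
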