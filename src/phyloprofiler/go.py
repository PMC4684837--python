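"""Gene Ontology term sets attached to genes.

Terms are treated as atomic identifiers ("GO:" + 7 digits), each tagged with
its ontology domain: C (cellular component), F (molecular function) or
P (biological process). No ontology-graph semantics are used; two functions
are compared purely as sets of tagged terms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

DOMAINS = ("C", "F", "P")

_TERM_RE = re.compile(r"^GO:\d{7}$")
_SERIALIZED_RE = re.compile(r"^(GO:\d{7})\[([CFP])\]$")

# a tagged term is a (go_id, domain) tuple
TaggedTerm = tuple[str, str]


class FunctionParseError(ValueError):
    """Raised for malformed GO-term annotations, naming the offending line."""


def validate_term(term: str, domain: str) -> None:
    if not _TERM_RE.match(term):
        raise FunctionParseError(f"malformed GO identifier: {term!r}")
    if domain not in DOMAINS:
        raise FunctionParseError(f"unknown GO domain {domain!r} (expected C, F or P)")


@dataclass(frozen=True)
class FunctionRecord:
    """A gene's annotated function: a set of domain-tagged GO terms."""

    gene_id: str
    terms: frozenset[TaggedTerm]

    def __post_init__(self) -> None:
        for term, domain in self.terms:
            validate_term(term, domain)

    def filtered(self, domain: str | None) -> frozenset[TaggedTerm]:
        """Terms restricted to one domain (C, F or P); all terms if None."""
        if domain is None:
            return self.terms
        if domain not in DOMAINS:
            raise ValueError(f"unknown GO domain {domain!r}")
        return frozenset(t for t in self.terms if t[1] == domain)


def filter_terms(
    terms: Iterable[TaggedTerm], domain: str | None
) -> frozenset[TaggedTerm]:
    if domain is None:
        return frozenset(terms)
    if domain not in DOMAINS:
        raise ValueError(f"unknown GO domain {domain!r}")
    return frozenset(t for t in terms if t[1] == domain)


def serialize_terms(terms: Iterable[TaggedTerm]) -> str:
    """Canonical text form: 'GO:0000001[F];GO:0000002[P]', sorted."""
    return ";".join(f"{t}[{d}]" for t, d in sorted(terms))


def parse_terms(text: str) -> frozenset[TaggedTerm]:
    out = set()
    for token in filter(None, (p.strip() for p in text.split(";"))):
        m = _SERIALIZED_RE.match(token)
        if not m:
            raise FunctionParseError(
                f"malformed term {token!r} (expected 'GO:XXXXXXX[C|F|P]')"
            )
        out.add((m.group(1), m.group(2)))
    return frozenset(out)


def read_functions_tsv(path: str | Path) -> dict[str, FunctionRecord]:
    """Read a gene-function table: gene_id <TAB> semicolon-joined tagged terms.

    A header line 'gene_id<TAB>terms' is permitted. Malformed rows raise
    :class:`FunctionParseError` naming the line number.
    """
    records: dict[str, FunctionRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith("gene_id"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FunctionParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            gene_id, terms_text = parts
            if gene_id in records:
                raise FunctionParseError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            try:
                terms = parse_terms(terms_text)
            except FunctionParseError as exc:
                raise FunctionParseError(f"{path}:{lineno}: {exc}") from None
            records[gene_id] = FunctionRecord(gene_id, terms)
    return records


def write_functions_tsv(
    functions: Mapping[str, FunctionRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tterms\n")
        for gene_id in sorted(functions):
            fh.write(f"{gene_id}\t{serialize_terms(functions[gene_id].terms)}\n")
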