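"""Nucleotide sequences, substitution schemes and FASTA I/O.

The scoring scheme distinguishes purines (A, G) from pyrimidines (C, T):
identical bases score highest, within-class substitutions (transitions)
score intermediate, cross-class substitutions (transversions) score lowest.
``N`` is treated as a mismatch against everything, including itself.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGTN"

_ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE_TABLE[ord(_c)] = _i
    _ENCODE_TABLE[ord(_c.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# purine/pyrimidine class per code: A=0,G=2 purines; C=1,T=3 pyrimidines; N=4 neither
_BASE_CLASS = {0: 0, 2: 0, 1: 1, 3: 1, 4: 2}


class InvalidSequenceError(ValueError):
    """Raised for sequences violating the {A,C,G,T,N} alphabet or emptiness rules."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified nucleotide sequence over the alphabet {A, C, G, T, N}."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        arr = np.frombuffer(self.residues.encode("ascii"), dtype=np.uint8)
        if np.any(_ENCODE_TABLE[arr] == 255):
            bad = sorted(set(self.residues) - set(ALPHABET))
            raise InvalidSequenceError(
                f"sequence {self.id!r} contains characters outside {{A,C,G,T,N}}: {bad}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def encoded(self) -> np.ndarray:
        """Residues as a uint8 code array (A=0, C=1, G=2, T=3, N=4)."""
        arr = np.frombuffer(self.residues.encode("ascii"), dtype=np.uint8)
        return np.ascontiguousarray(_ENCODE_TABLE[arr])

    def reverse_complement(self) -> "NucleotideSequence":
        rc = self.residues.translate(_COMPLEMENT)[::-1]
        return NucleotideSequence(self.id, rc, self.description)

    def base_counts(self) -> dict[str, int]:
        return {b: self.residues.count(b) for b in ALPHABET}


@dataclass(frozen=True)
class SubstitutionScheme:
    """Purine/pyrimidine nucleotide scoring scheme with affine gaps.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``; terminal gaps
    are penalised like internal ones (true end-to-end global alignment).

    Parameters
    ----------
    match_score : score for identical bases.
    transition_score : score for a within-class substitution (A<->G, C<->T).
    transversion_score : score for a cross-class substitution; also used for
        any pair involving N.
    gap_open, gap_extend : non-positive affine gap penalties.
    """

    match_score: int = 2
    transition_score: int = 1
    transversion_score: int = -2
    gap_open: int = -6
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if not (self.match_score >= self.transition_score >= self.transversion_score):
            raise ValueError(
                "scheme must satisfy match >= transition (same-class) >= "
                "transversion (cross-class)"
            )
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")

    @functools.cache
    def matrix(self) -> np.ndarray:
        """5x5 symmetric score matrix over the coded alphabet A,C,G,T,N."""
        m = np.empty((5, 5), dtype=np.int64)
        for i in range(5):
            for j in range(5):
                ci, cj = _BASE_CLASS[i], _BASE_CLASS[j]
                if i == j and i != 4:
                    m[i, j] = self.match_score
                elif ci == cj and ci != 2:
                    m[i, j] = self.transition_score
                else:
                    m[i, j] = self.transversion_score
        m.setflags(write=False)
        return m

    @classmethod
    def from_dict(cls, d: Mapping) -> "SubstitutionScheme":
        return cls(**{k: int(v) for k, v in d.items()})


DEFAULT_SCHEME = SubstitutionScheme()


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a (multi-record) nucleotide FASTA file."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(NucleotideSequence(rec.id, str(rec.seq), rec.description))
    return out


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description or "")
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def iter_fasta(path: str | Path) -> Iterator[NucleotideSequence]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield NucleotideSequence(rec.id, str(rec.seq), rec.description)
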