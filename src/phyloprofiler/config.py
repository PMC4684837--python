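"""Run configuration and deterministic random-number management.

Every stochastic stage of the pipeline draws from a generator forked off a
single top-level seed together with a string context (for profile building,
the gene id and genome id). Forking is order-independent: the bit a gene
receives for a genome does not depend on which (gene, genome) pairs were
processed before it, so results are reproducible under any scheduling.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

MAX_SEED = 2**31 - 1


def fork_rng(seed: int, *context: object) -> np.random.Generator:
    """Deterministic, order-independent child generator for a seed + context.

    The context tokens (typically gene and genome identifiers) are hashed with
    SHA-256 into the entropy pool, so any distinct context yields an
    independent stream while identical (seed, context) pairs always reproduce
    the same stream.
    """
    digest = hashlib.sha256(
        "\x1f".join(str(t) for t in context).encode("utf-8")
    ).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32).tolist()
    ss = np.random.SeedSequence([int(seed) & MAX_SEED, *words])
    return np.random.default_rng(ss)


def as_rng(rng: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce an int seed (or None) to a numpy Generator; pass through Generators."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class RunConfig:
    """All tunables of the pipeline with their default values.

    Scoring and search defaults follow the package's purine/pyrimidine scheme;
    the significance thresholds are the method's published operating point:
    alignment significance cutoff z_min = 5.0, profile-similarity cutoff
    p0 = 1e-7 (calibrated for a ~1200-genome panel), prediction-list depth
    k_top = 5, and 1000 Monte-Carlo shuffles per alignment.
    """

    # substitution scheme / gaps
    match_score: int = 2
    transition_score: int = 1
    transversion_score: int = -2
    gap_open: int = -6
    gap_extend: int = -2
    # local candidate search
    seed_k: int = 11
    sweep: Sequence[Sequence[int]] = ((1, -2), (1, -3), (2, -3))
    min_local_score: int = 25
    xdrop: int = 20
    max_regions: int = 3
    # significance
    n_shuffles: int = 1000
    z_min: float = 5.0
    # profile comparison / prediction
    p0: float = 1e-7
    k_top: int = 5
    # misc
    min_gene_length: int = 90
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p0 < 1):
            raise ValueError("p0 must lie in (0, 1)")
        if self.k_top < 1:
            raise ValueError("k_top must be >= 1")
        if self.n_shuffles < 2:
            raise ValueError("n_shuffles must be >= 2")
        if self.seed_k < 4:
            raise ValueError("seed_k must be >= 4")
        if not self.sweep:
            raise ValueError("sweep must be non-empty")
        self.sweep = tuple((int(r), int(p)) for r, p in self.sweep)
        if not (0 <= self.seed <= MAX_SEED):
            raise ValueError(f"seed must lie in [0, {MAX_SEED}]")

    def scheme(self):
        from .sequences import SubstitutionScheme

        return SubstitutionScheme(
            match_score=self.match_score,
            transition_score=self.transition_score,
            transversion_score=self.transversion_score,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sweep"] = [list(s) for s in self.sweep]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
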