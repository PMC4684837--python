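"""Phylogenetic profiles: binary gene presence/absence over a reference panel.

A gene's profile over an ordered panel of N reference genomes has a 1 in
position i exactly when some candidate region of genome i yields a global
alignment whose Monte-Carlo Z-score reaches the significance cutoff
(z_min = 5.0 at the published operating point). The profile database pairs
each profile with the gene's known GO-term function record and persists both
as plain TSV beside the ordered panel manifest (profile positions are
meaningless without the panel order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .align import (
    DEFAULT_SWEEP,
    DegenerateNullError,
    extend_to_global,
    find_candidate_regions,
    monte_carlo_significance,
)
from .config import fork_rng
from .go import FunctionRecord, read_functions_tsv, write_functions_tsv
from .sequences import DEFAULT_SCHEME, NucleotideSequence, SubstitutionScheme

logger = logging.getLogger(__name__)

__all__ = [
    "PhylogeneticProfile",
    "ProfileDatabase",
    "ReferencePanel",
    "build_database",
    "build_profile",
    "profile_bit",
    "restrict_panel",
]

MIN_GENE_LENGTH = 90  # below this, Monte-Carlo normality is dubious; flagged


@dataclass(frozen=True)
class ReferencePanel:
    """Ordered, unique genome identifiers defining profile coordinates."""

    genome_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genome_ids", tuple(self.genome_ids))
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValueError("panel genome ids must be unique")

    @property
    def N(self) -> int:
        return len(self.genome_ids)

    def save(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{g}\n" for g in self.genome_ids))

    @classmethod
    def load(cls, path: str | Path) -> "ReferencePanel":
        ids = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        return cls(tuple(ids))


@dataclass(frozen=True)
class PhylogeneticProfile:
    """Binary presence vector of one gene over the reference panel."""

    gene_id: str
    bits: np.ndarray  # uint8 vector of length N
    flagged_short: bool = False

    def __post_init__(self) -> None:
        arr = np.ascontiguousarray(np.asarray(self.bits, dtype=np.uint8))
        if arr.ndim != 1 or (arr.size and arr.max() > 1):
            raise ValueError("profile bits must be a 1-D 0/1 vector")
        arr.setflags(write=False)
        object.__setattr__(self, "bits", arr)

    @property
    def n_ones(self) -> int:
        return int(self.bits.sum())

    def bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    @classmethod
    def from_bitstring(cls, gene_id: str, s: str) -> "PhylogeneticProfile":
        return cls(gene_id, np.frombuffer(s.encode(), np.uint8) - ord("0"))


def profile_bit(
    gene: NucleotideSequence,
    genome: NucleotideSequence,
    *,
    scheme: SubstitutionScheme = DEFAULT_SCHEME,
    z_min: float = 5.0,
    n_shuffles: int = 1000,
    seed: int = 0,
    sweep: Sequence[tuple[int, int]] = DEFAULT_SWEEP,
    k: int = 11,
    min_local_score: int = 25,
    xdrop: int = 20,
    max_regions: int = 3,
) -> int:
    """1 iff any candidate region of ``genome`` aligns to ``gene`` with Z >= z_min.

    Candidate regions are ranked by their local seed score and at most
    ``max_regions`` of them are extended to gene-length global alignments and
    tested; the search stops at the first significant one. The Monte-Carlo
    generator is forked deterministically from (seed, gene id, genome id), so
    the bit does not depend on processing order. A degenerate shuffle null
    (zero variance) counts as 0 with a logged warning.
    """
    regions = find_candidate_regions(
        gene, genome, sweep, k=k, min_score=min_local_score, xdrop=xdrop
    )
    for idx, region in enumerate(regions[:max_regions]):
        rng = fork_rng(seed, gene.id, genome.id, idx)
        window, _ = extend_to_global(gene, genome, region, scheme)
        try:
            sig = monte_carlo_significance(
                gene, window, scheme, n_shuffles=n_shuffles, rng=rng
            )
        except DegenerateNullError:
            logger.warning(
                "degenerate shuffle null for gene %s vs genome %s; scoring 0",
                gene.id,
                genome.id,
            )
            continue
        if sig.Z >= z_min:
            return 1
    return 0


def build_profile(
    gene: NucleotideSequence,
    panel: ReferencePanel,
    genomes: Mapping[str, NucleotideSequence],
    **kwargs,
) -> PhylogeneticProfile:
    """Build the gene's binary profile over the panel (see :func:`profile_bit`).

    ``genomes`` must cover every panel id. Genes shorter than
    ``MIN_GENE_LENGTH`` are profiled but flagged, since the shuffle null is
    poorly resolved for very short sequences.
    """
    missing = [g for g in panel.genome_ids if g not in genomes]
    if missing:
        raise ValueError(f"genome sequences missing for panel ids: {missing}")
    bits = np.zeros(panel.N, dtype=np.uint8)
    for i, genome_id in enumerate(panel.genome_ids):
        bits[i] = profile_bit(gene, genomes[genome_id], **kwargs)
    flagged = len(gene) < MIN_GENE_LENGTH
    if flagged:
        logger.warning(
            "gene %s is shorter than %d nt; profile flagged", gene.id, MIN_GENE_LENGTH
        )
    return PhylogeneticProfile(gene.id, bits, flagged_short=flagged)


@dataclass
class ProfileDatabase:
    """Profiles plus function records of genes with known functions."""

    panel: ReferencePanel
    profiles: dict[str, PhylogeneticProfile]
    functions: dict[str, FunctionRecord]

    def __post_init__(self) -> None:
        for gene_id, profile in self.profiles.items():
            if len(profile.bits) != self.panel.N:
                raise ValueError(
                    f"profile {gene_id} has length {len(profile.bits)}, "
                    f"panel size is {self.panel.N}"
                )
            if gene_id not in self.functions:
                raise ValueError(f"profiled gene {gene_id} has no function record")

    def __len__(self) -> int:
        return len(self.profiles)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.panel.save(directory / "panel.txt")
        with open(directory / "profiles.tsv", "w") as fh:
            fh.write("gene_id\tbits\n")
            for gene_id in sorted(self.profiles):
                fh.write(f"{gene_id}\t{self.profiles[gene_id].bitstring()}\n")
        write_functions_tsv(self.functions, directory / "functions.tsv")
        with open(directory / "meta.yaml", "w") as fh:
            yaml.safe_dump(
                {"n_genes": len(self.profiles), "panel_size": self.panel.N}, fh
            )

    @classmethod
    def load(cls, directory: str | Path) -> "ProfileDatabase":
        directory = Path(directory)
        panel = ReferencePanel.load(directory / "panel.txt")
        profiles: dict[str, PhylogeneticProfile] = {}
        with open(directory / "profiles.tsv") as fh:
            header = fh.readline()
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                gene_id, bits = line.split("\t")
                profiles[gene_id] = PhylogeneticProfile.from_bitstring(gene_id, bits)
        functions = read_functions_tsv(directory / "functions.tsv")
        functions = {g: functions[g] for g in profiles}
        return cls(panel, profiles, functions)


def build_database(
    genes: Sequence[NucleotideSequence],
    functions: Mapping[str, FunctionRecord],
    panel: ReferencePanel,
    genomes: Mapping[str, NucleotideSequence],
    **kwargs,
) -> ProfileDatabase:
    """Profile every gene with a known function against the panel.

    Genes without a (non-empty) function record are skipped with a logged
    count; duplicate gene ids are an error.
    """
    seen: set[str] = set()
    for gene in genes:
        if gene.id in seen:
            raise ValueError(f"duplicate gene id {gene.id!r} in input genes")
        seen.add(gene.id)
    profiles: dict[str, PhylogeneticProfile] = {}
    kept_functions: dict[str, FunctionRecord] = {}
    skipped = 0
    for gene in genes:
        record = functions.get(gene.id)
        if record is None or not record.terms:
            skipped += 1
            continue
        profiles[gene.id] = build_profile(gene, panel, genomes, **kwargs)
        kept_functions[gene.id] = record
    if skipped:
        logger.info("skipped %d genes without GO terms", skipped)
    return ProfileDatabase(panel, profiles, kept_functions)


def restrict_panel(
    db: ProfileDatabase, drop_genome_ids: Iterable[str]
) -> ProfileDatabase:
    """Drop panel columns (e.g. the query's own genomes) and rebuild counts.

    Used in evaluation to exclude query genomes from the reference group so a
    gene is not trivially supported by its own genome.
    """
    drop = set(drop_genome_ids)
    keep_idx = [i for i, g in enumerate(db.panel.genome_ids) if g not in drop]
    panel = ReferencePanel(tuple(db.panel.genome_ids[i] for i in keep_idx))
    idx = np.array(keep_idx, dtype=np.intp)
    profiles = {
        gene_id: PhylogeneticProfile(
            gene_id, profile.bits[idx], flagged_short=profile.flagged_short
        )
        for gene_id, profile in db.profiles.items()
    }
    return ProfileDatabase(panel, profiles, dict(db.functions))
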