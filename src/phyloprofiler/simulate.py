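"""Synthetic reference panels with planted gene families and ground truth.

The generator emulates the data regime the profiling method assumes: a panel
of bacterial genomes in which families of genes co-occur because they serve
one genetic process. Genes are organised into groups ("pathways"); each
group draws one presence/absence pattern over the panel, every gene of the
group is planted (as an independently drawn ancestral sequence, mutated at a
controlled divergence rate, on a random strand) into exactly the genomes its
pattern selects, and all genes of a group share one GO-term set. Intergenic
background is i.i.d. uniform over {A, C, G, T}, which keeps the k-mer
seed-hit null analytically tractable.

Everything is deterministic given the seed, and the returned truth tables
let tests verify each pipeline stage against the planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .config import as_rng
from .evaluation import Pathway, write_pathways_tsv
from .go import FunctionRecord, write_functions_tsv
from .profiles import ReferencePanel
from .sequences import NucleotideSequence, write_fasta

__all__ = [
    "Planting",
    "SyntheticPanel",
    "SyntheticTruth",
    "generate_panel",
    "generate_random_profiles",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_CODE = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _BASE_CODE[_b] = _i


@dataclass(frozen=True)
class Planting:
    """One planted gene copy: where a family member was inserted."""

    genome_id: str
    gene_id: str
    start: int
    end: int
    strand: str


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-gene presence patterns and all plantings."""

    patterns: dict[str, np.ndarray]  # gene_id -> 0/1 vector over the panel
    groups: dict[str, str]  # gene_id -> group (pathway) id
    divergence: float
    plantings: list[Planting]

    def recomputed_patterns(self, panel: ReferencePanel) -> dict[str, np.ndarray]:
        """Presence patterns rebuilt from the planting coordinates."""
        index = {g: i for i, g in enumerate(panel.genome_ids)}
        out = {g: np.zeros(panel.N, dtype=np.uint8) for g in self.patterns}
        for pl in self.plantings:
            out[pl.gene_id][index[pl.genome_id]] = 1
        return out


@dataclass
class SyntheticPanel:
    """A generated panel: genomes, genes, labels, pathways and the truth."""

    panel: ReferencePanel
    genomes: dict[str, NucleotideSequence]
    genes: list[NucleotideSequence]
    functions: dict[str, FunctionRecord]
    pathways: list[Pathway]
    truth: SyntheticTruth

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        (directory / "genomes").mkdir(parents=True, exist_ok=True)
        self.panel.save(directory / "panel.txt")
        for genome_id, genome in self.genomes.items():
            write_fasta([genome], directory / "genomes" / f"{genome_id}.fasta")
        write_fasta(self.genes, directory / "genes.fasta")
        write_functions_tsv(self.functions, directory / "functions.tsv")
        write_pathways_tsv(self.pathways, directory / "pathways.tsv")
        with open(directory / "truth_patterns.tsv", "w") as fh:
            fh.write("gene_id\tgroup_id\tbits\tdivergence\n")
            for gene_id in sorted(self.truth.patterns):
                bits = "".join(map(str, self.truth.patterns[gene_id]))
                fh.write(
                    f"{gene_id}\t{self.truth.groups[gene_id]}\t{bits}\t"
                    f"{self.truth.divergence}\n"
                )
        with open(directory / "truth_plantings.tsv", "w") as fh:
            fh.write("genome_id\tgene_id\tstart\tend\tstrand\n")
            for pl in self.truth.plantings:
                fh.write(
                    f"{pl.genome_id}\t{pl.gene_id}\t{pl.start}\t{pl.end}\t{pl.strand}\n"
                )


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, residues: str, rate: float) -> str:
    """I.i.d. substitutions at ``rate``, uniform over the three alternatives."""
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    if hit.any():
        # shift by 1..3 in the base cycle A->C->G->T, i.e. uniform over the
        # three alternative bases
        codes = _BASE_CODE[arr]
        shifts = rng.integers(1, 4, size=arr.size)
        arr[hit] = _BASES[(codes + shifts) % 4][hit]
    return arr.tobytes().decode("ascii")


def generate_panel(
    n_genomes: int = 20,
    genome_length: int = 50_000,
    n_groups: int = 10,
    genes_per_group: int = 5,
    gene_length: int = 300,
    presence_density: float = 0.5,
    divergence: float = 0.1,
    noise_bitflip: float = 0.0,
    rng: int | np.random.Generator | None = None,
) -> SyntheticPanel:
    """Generate a reference panel with planted, co-occurring gene families.

    Each of the ``n_groups`` groups draws one Bernoulli(``presence_density``)
    presence pattern over the panel (redrawn until it has at least two ones,
    since a gene occurring once can never co-occur); each member gene gets an
    independent random ancestral sequence, the group pattern with per-bit
    flip probability ``noise_bitflip``, and the group's shared GO-term set.
    Mutated copies (substitution rate ``divergence``, random strand) are
    planted at non-overlapping random positions of the selected genomes.
    """
    gen = as_rng(rng)
    if not (0 <= divergence <= 0.3):
        raise ValueError("divergence must lie in [0, 0.3]")
    if not (0 < presence_density < 1):
        raise ValueError("presence_density must lie in (0, 1)")
    worst_load = n_groups * genes_per_group * gene_length
    if worst_load > 0.8 * genome_length:
        raise ValueError(
            f"infeasible packing: up to {worst_load} planted bases do not fit "
            f"into genomes of length {genome_length}"
        )
    genome_ids = [f"genome_{i:02d}" for i in range(n_genomes)]
    panel = ReferencePanel(tuple(genome_ids))

    genes: list[NucleotideSequence] = []
    functions: dict[str, FunctionRecord] = {}
    pathways: list[Pathway] = []
    patterns: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    per_genome_genes: dict[str, list[NucleotideSequence]] = {g: [] for g in genome_ids}

    for g in range(n_groups):
        group_id = f"PWY_{g:04d}"
        while True:
            group_pattern = (gen.random(n_genomes) < presence_density).astype(np.uint8)
            if group_pattern.sum() >= 2:
                break
        term_set = frozenset(
            {(f"GO:{2 * g + 1:07d}", "F"), (f"GO:{2 * g + 2:07d}", "P")}
        )
        member_ids = []
        for m in range(genes_per_group):
            gene_id = f"g{g:02d}_{m:02d}"
            member_ids.append(gene_id)
            ancestor = NucleotideSequence(gene_id, _random_sequence(gen, gene_length))
            genes.append(ancestor)
            functions[gene_id] = FunctionRecord(gene_id, term_set)
            pattern = group_pattern.copy()
            if noise_bitflip > 0:
                flips = gen.random(n_genomes) < noise_bitflip
                pattern = np.where(flips, 1 - pattern, pattern).astype(np.uint8)
            patterns[gene_id] = pattern
            groups[gene_id] = group_id
            for i, present in enumerate(pattern):
                if present:
                    per_genome_genes[genome_ids[i]].append(ancestor)
        pathways.append(Pathway(group_id, frozenset(member_ids)))

    genomes: dict[str, NucleotideSequence] = {}
    plantings: list[Planting] = []
    for genome_id in genome_ids:
        background = np.frombuffer(
            _random_sequence(gen, genome_length).encode("ascii"), dtype=np.uint8
        ).copy()
        placed: list[tuple[int, int]] = []
        for ancestor in per_genome_genes[genome_id]:
            copy = _mutate(gen, ancestor.residues, divergence)
            strand = "+" if gen.random() < 0.5 else "-"
            if strand == "-":
                copy = NucleotideSequence("tmp", copy).reverse_complement().residues
            start = _place(gen, genome_length, len(copy), placed)
            placed.append((start, start + len(copy)))
            background[start : start + len(copy)] = np.frombuffer(
                copy.encode("ascii"), dtype=np.uint8
            )
            plantings.append(
                Planting(genome_id, ancestor.id, start, start + len(copy), strand)
            )
        genomes[genome_id] = NucleotideSequence(
            genome_id, background.tobytes().decode("ascii")
        )
    truth = SyntheticTruth(
        patterns=patterns, groups=groups, divergence=divergence, plantings=plantings
    )
    return SyntheticPanel(panel, genomes, genes, functions, pathways, truth)


def _place(
    rng: np.random.Generator,
    genome_length: int,
    length: int,
    placed: list[tuple[int, int]],
    max_attempts: int = 10_000,
) -> int:
    for _ in range(max_attempts):
        start = int(rng.integers(0, genome_length - length + 1))
        end = start + length
        if all(end <= s or start >= e for s, e in placed):
            return start
    raise ValueError("infeasible packing: could not place a gene without overlap")


def generate_random_profiles(
    n_pairs: int,
    N: int,
    density_range: tuple[float, float] = (0.05, 0.5),
    rng: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Independent Bernoulli profile pairs for null calibration.

    Each vector draws its own density uniformly from ``density_range``.
    Returns two (n_pairs, N) uint8 arrays; row i of each is one pair.
    """
    gen = as_rng(rng)
    lo, hi = density_range
    if not (0 < lo <= hi < 1):
        raise ValueError("density_range must lie within (0, 1)")
    d1 = gen.uniform(lo, hi, size=(n_pairs, 1))
    d2 = gen.uniform(lo, hi, size=(n_pairs, 1))
    a = (gen.random((n_pairs, N)) < d1).astype(np.uint8)
    b = (gen.random((n_pairs, N)) < d2).astype(np.uint8)
    return a, b
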