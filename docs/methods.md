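# Methods

## The problem and the model

`phyloprofiler` predicts biological functions for bacterial genes from
co-occurrence across genomes rather than from direct sequence similarity to
an annotated gene. The premise is the classical phylogenetic-profiling
argument: a gene rarely acts alone; the genes of one genetic process are
inherited together, so genes of the same process show up in the same subsets
of genomes. A gene whose best database hit is a weak (<70% identity) match
may still be annotated confidently if its *presence pattern* across a genome
panel matches the pattern of genes with known functions.

The pipeline has four stages.

### 1. Homology detection: global alignment with a Monte-Carlo null

For a gene *g* and genome *G*, candidate regions are proposed by a
seed-and-extend local search: exact *k*-mer seeds (default *k* = 11, both
strands) are extended without gaps under several (reward, penalty) settings
(default sweep {(1, −2), (1, −3), (2, −3)}) with an X-drop rule; segments
reaching a minimum local score (default 25) become candidates, and
overlapping candidates are merged. This plays the role a fast heuristic
local aligner plays in large-scale practice, while keeping the package
self-contained and its null behaviour analytically checkable (the expected
chance seed count per position is 0.25^k for i.i.d. backgrounds).

Local similarity alone often reflects a shared domain, not gene-level
homology, so each candidate is re-scored *globally*: a genome window of
exactly the gene's length, centred on the candidate region (clipped at
genome ends, reverse-complemented for minus-strand candidates), is aligned
end-to-end against the full gene with the Needleman–Wunsch/Gotoh algorithm
under a purine/pyrimidine (PuPy) substitution scheme — identical bases +2,
within-class substitutions (A↔G, C↔T) +1, cross-class −2, affine gaps with
open −6 and extend −2 (a gap of length L costs open + (L−1)·extend; terminal
gaps are penalised). `N` scores as a cross-class mismatch against
everything. All scores are configurable; the class ordering
match ≥ transition ≥ transversion is enforced.

The raw score F is calibrated by Monte Carlo: the gene is shuffled
(uniformly, preserving base composition) `n_shuffles` times (default 1000;
200 in the desk-scale runs below), each shuffle is aligned against the same
window, and

    Z = (F − M(F)) / sqrt(D(F)),

where M and D are the sample mean and *unbiased* sample variance (divisor
n−1) of the shuffled scores. Z measures how far the real gene's score rises
above what its composition alone produces. The detection cutoff is
Z ≥ z_min with z_min = 5.0. Because the real score of an *unrelated*
window is exchangeable with its shuffles, Z is approximately standard normal
under the null — a property the acceptance checks verify empirically
(mean within ±0.15, sd within [0.85, 1.15] over 1000 replicates).

A second shuffle, used for false-annotation experiments rather than for the
null, permutes bases only within codon-position classes (positions ≡ 0, 1, 2
mod 3 over complete codons; trailing bases stay in place), preserving the
triplet periodicity of coding sequences.

### 2. Profiles

The gene's phylogenetic profile over an ordered reference panel of N
genomes is the binary vector with bit *i* = 1 iff some candidate region of
genome *i* reaches Z ≥ z_min (at most `max_regions` = 3 candidates are
tested per genome, best seed score first, stopping at the first success).
A gene's own source genome keeps its bit — it is a genuine occurrence;
evaluation procedures that need to avoid self-support drop the query's
genomes from the panel (`restrict_panel`) or its own database entry
(leave-own-gene-out). Genes shorter than 90 nt are profiled but flagged:
the shuffle null is poorly resolved for very short sequences. Every
(gene, genome) pair forks its own random generator from the top-level seed
and the two identifiers, so profiles are reproducible and independent of
processing order and thread count.

### 3. Profile comparison: exact hypergeometric co-occurrence

For two profiles with n1 and n2 ones and n12 shared one-positions over a
panel of size N, the similarity measure is the exact upper tail

    P(X ≥ n12) = Σ_{k=n12}^{min(n1,n2)} C(n1,k) · C(N−n1, n2−k) / C(N, n2),

the chance of co-occurring at least n12 times if the two genes occurred
independently. The tail is evaluated in log space: the first term by
log-gamma, subsequent terms by the exact pmf ratio recurrence, summed with
a max-shifted compensated sum. Arguments are canonicalised (n1 ≤ n2) so the
comparison is bit-exact symmetric. Values below 1e-300 are clamped to
1e-300 and flagged; ordering below the clamp is irrelevant at any usable
threshold. Accuracy is exact to ~1e-14 against placement enumeration for
panels up to 12 and ~1e-11 relative against an independent library
implementation across panel sizes to 2000.

Pairs with P ≤ P0 are deemed related. The published operating point
P0 = 1e-7 is calibrated for a ~1200-genome panel so that at most ~1 in 1e7
random comparisons passes; `calibrate_p0` measures that rate empirically
(1e6 random pairs at N = 1204 stream through the same comparison code).

### 4. Prediction and evaluation

Database genes passing P0 vote with their complete GO-term sets (terms are
atomic "GO:XXXXXXX" identifiers tagged C/F/P; no ontology-graph reasoning).
Identical term sets merge into one prediction entry keeping the smallest P
and all supporting genes; entries are sorted ascending by P, with
deterministic tie-breaks (larger n12, then lexicographic gene id). Queries
whose profiles have fewer than two ones are reported unannotatable
("profile too sparse") — they cannot reach any realistic P0.

Evaluation reproduces the standard subset algebra: C0 all genes, C1 with
known functions, C2 with predictions, C3 = C2 − C1 (newly annotated),
C4 = C1 − C2, C5 = C1 ∩ C2, C6 ⊆ C5 where the known function matches one of
the top-K predictions (K = 5), C7 = C5 − C6. Matching is *perfect*
(set equality) or *fuzzy* (non-empty intersection), restricted by default to
the molecular-function domain F; the C1/C2 membership tests apply the same
domain filter, so a gene whose known annotation has no F-domain term does
not count as "known" in an F-domain evaluation. The rank distribution
records, per C5 gene, the minimal prediction-list prefix containing the
known function. Pathway coverage maps each gene to its smallest containing
pathway (pathways with more than 30 genes are dropped; ties break
lexicographically), defines the pathway length Q as the number of *distinct
member functions* (term sets, not genes — the coverage denominator counts
functions), and scores the fraction of those functions found in the gene's
top-Q and top-2Q prediction lists, averaged within Q bins
1–4, 5–9, …, 25–30.

## Synthetic data: what it emulates and what it does not

`generate_panel` produces the study conditions used throughout the tests:
20 genomes × 50 kb, 10 groups × 5 genes, gene length 300 nt, presence
density 0.5, divergence 0.1, bit-flip noise 0. Each group draws one
presence pattern (redrawn until it has ≥ 2 ones); each member gene is an
independent random ancestral sequence planted — with i.i.d. substitutions at
the divergence rate, uniform over the three alternative bases, on a random
strand, at non-overlapping random positions — into exactly the genomes the
pattern selects. All genes of a group share one GO-term set (one F and one
P term), distinct across groups; each group is also emitted as a pathway.

The generator captures the features the method relies on: co-occurrence of
functionally linked genes, sequence divergence between homologs, strand
ambiguity, and an unstructured intergenic background that makes seed-hit
rates and alignment nulls analytically predictable. It deliberately omits
phylogenetic correlation (presence patterns are drawn i.i.d., not on a
tree), compositional bias, repeats, paralogy and horizontal transfer.
Passing the recovery tests therefore shows the machinery is correct and
well-calibrated, not that real-genome accuracy matches the synthetic rates:
real panels have correlated genomes, skewed base composition and paralogs,
all of which reduce attainable precision.

## Parameter choices at desk scale

- **Monte-Carlo sample size 200** (instead of the default 1000) for the
  synthetic recovery and null-calibration runs. At n = 200 the extra
  variance inflates sd(Z) by < 1%, far inside the acceptance bands, and the
  planted-copy Z values sit orders of magnitude above z_min = 5.
- **P0 = 1e-3 on the 20-genome panel.** P0 must scale with the panel: the
  smallest attainable P at N = 20 is 1/C(20,10) ≈ 5.4e-6, so the published
  1e-7 (tuned for N ≈ 1200) would reject everything. 1e-3 admits any exact
  pattern match with ≥ 3 shared ones while keeping the expected chance
  matches per query at ~49 × 1e-3 ≈ 0.05, preserving the spirit of the
  published calibration (chance pass rate ≪ 1 per query).
- **Local-search minimum score 25** under the default sweep: an exact
  11-mer seed alone scores 11–22 depending on the reward, so random seeds
  rarely pass, while a 300-nt homolog at 10–15% divergence scores in the
  hundreds. False candidates that do pass are cheap: the Z ≥ 5 cutoff
  removes them (chance rate ~3e-7 per test under normality).
- **Window choice for global alignment**: a query-length window centred on
  the candidate region. "Global" needs a bounded target; a gene-length
  window makes the score comparable across genomes and keeps the all-match
  score equal to gene length × match score.

## Numerical and degenerate-input conventions

- Coordinates are 0-based half-open internally; reports are 1-based
  inclusive only where explicitly human-readable.
- A zero-variance shuffle null (e.g. a homopolymer gene) raises a
  degenerate-null error in `z_score`; profile building logs it and scores
  the bit 0.
- `hypergeometric_p` returns exactly 1.0 when n12 is at or below the
  support's lower bound (including n12 = 0), avoiding float drift in the
  "certain" case.
- An empty panel yields an empty profile with n_ones = 0; empty sequences
  are rejected by alignment operations.
- Ties anywhere (equal P, equal pathway sizes) break deterministically as
  described above, so runs are bit-for-bit reproducible for a fixed seed,
  including under thread parallelism.

## Known limitations

- The seed-and-extend search can miss homologs whose divergence leaves no
  exact 11-mer (expected surviving seeds ≈ (L−k+1)·(1−d)^k; at d = 0.2 and
  L = 300 about 25 remain, at d = 0.3 about 8). The sweep mitigates but
  does not remove this; the generator therefore bounds divergence at 0.3.
- Profile bits are binary; copy number and partial matches are discarded by
  design.
- GO terms are opaque atoms: a prediction of a parent term does not match a
  child term under either matching mode.
- The hypergeometric null assumes genome-wise independence; closely related
  genomes violate it, which is why reference panels should be deduplicated
  at the strain level before profiling.
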