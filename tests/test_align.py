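"""Alignment, candidate search, shuffles and Monte-Carlo significance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phyloprofiler import (
    DegenerateNullError,
    NucleotideSequence,
    SubstitutionScheme,
    extend_to_global,
    find_candidate_regions,
    global_alignment_score,
    monte_carlo_significance,
    shuffle_preserving_triplet_periodicity,
    shuffle_sequence,
    z_score,
)
from phyloprofiler.align import CandidateRegion

from conftest import nw_oracle, nw_path_enumeration, random_sequence

dna = st.text(alphabet="ACGT", min_size=1, max_size=10)


class TestGlobalAlignment:
    def test_identity_scores_all_match(self, small_scheme):
        seq = NucleotideSequence("a", "ACGTACGTAC")
        assert global_alignment_score(seq, seq, small_scheme) == 10 * 2

    def test_forced_single_path(self):
        # one match plus a gap of length 3: 2 + (-5 - 5 - 5) with linear gaps
        scheme = SubstitutionScheme(match_score=2, gap_open=-5, gap_extend=-5)
        q = NucleotideSequence("q", "ACGT")
        t = NucleotideSequence("t", "A")
        assert global_alignment_score(q, t, scheme) == -13

    def test_empty_sequence_rejected(self, small_scheme):
        q = NucleotideSequence("q", "ACGT")
        empty = NucleotideSequence("e", "")
        with pytest.raises(ValueError):
            global_alignment_score(q, empty, small_scheme)

    def test_n_scores_as_mismatch_to_everything(self, small_scheme):
        a = NucleotideSequence("a", "ANA")
        b = NucleotideSequence("b", "AAA")
        assert global_alignment_score(a, b, small_scheme) == 2 + (-2) + 2
        n2 = NucleotideSequence("n", "NN")
        assert global_alignment_score(n2, n2, small_scheme) == 2 * (-2)

    def test_path_enumeration_validates_memoised_oracle(self, small_scheme):
        rng = np.random.default_rng(42)
        for _ in range(12):
            a = random_sequence(rng, int(rng.integers(1, 5))).residues
            b = random_sequence(rng, int(rng.integers(1, 5))).residues
            assert nw_path_enumeration(a, b, small_scheme) == nw_oracle(a, b, small_scheme)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_edit_path_oracle(self, small_scheme, trial):
        rng = np.random.default_rng(1000 + trial)
        a = random_sequence(rng, int(rng.integers(1, 9)), "a")
        b = random_sequence(rng, int(rng.integers(1, 9)), "b")
        expected = nw_oracle(a.residues, b.residues, small_scheme)
        assert global_alignment_score(a, b, small_scheme) == expected

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(a=dna, b=dna)
    def test_symmetric_in_arguments(self, a, b):
        sa = NucleotideSequence("a", a)
        sb = NucleotideSequence("b", b)
        assert global_alignment_score(sa, sb) == global_alignment_score(sb, sa)

    def test_constant_shift_adds_k_c_on_gap_free_alignments(self):
        # equal lengths with prohibitive gap penalties force the diagonal path
        base = SubstitutionScheme(2, 1, -2, gap_open=-10_000, gap_extend=-10_000)
        c = 3
        shifted = SubstitutionScheme(2 + c, 1 + c, -2 + c, -10_000, -10_000)
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(2, 30))
            a = random_sequence(rng, n, "a")
            b = random_sequence(rng, n, "b")
            f0 = global_alignment_score(a, b, base)
            f1 = global_alignment_score(a, b, shifted)
            assert f1 - f0 == n * c

    def test_agrees_with_biotite_on_longer_sequences(self):
        align = pytest.importorskip("biotite.sequence.align")
        import biotite.sequence as bseq

        scheme = SubstitutionScheme()
        alph = bseq.NucleotideSequence.alphabet_unamb
        mat = align.SubstitutionMatrix(
            alph, alph, np.asarray(scheme.matrix()[:4, :4], dtype=np.int32)
        )
        rng = np.random.default_rng(9)
        for _ in range(8):
            a = random_sequence(rng, int(rng.integers(40, 120)), "a")
            b = random_sequence(rng, int(rng.integers(40, 120)), "b")
            ref = align.align_optimal(
                bseq.NucleotideSequence(a.residues),
                bseq.NucleotideSequence(b.residues),
                mat,
                gap_penalty=(scheme.gap_open, scheme.gap_extend),
                local=False,
                terminal_penalty=True,
                max_number=1,
            )[0].score
            assert global_alignment_score(a, b, scheme) == ref


class TestCandidateRegions:
    def test_planted_query_is_found(self):
        rng = np.random.default_rng(21)
        query = random_sequence(rng, 120, "q")
        genome = random_sequence(rng, 5000, "g")
        pos = 1000
        residues = genome.residues[:pos] + query.residues + genome.residues[pos + 120 :]
        genome = NucleotideSequence("g", residues)
        regions = find_candidate_regions(query, genome)
        overlaps = [
            max(0, min(r.end, pos + 120) - max(r.start, pos)) for r in regions
        ]
        assert max(overlaps, default=0) >= 0.9 * 120

    def test_reverse_complement_plant_found_on_minus_strand(self):
        rng = np.random.default_rng(22)
        query = random_sequence(rng, 120, "q")
        genome = random_sequence(rng, 5000, "g")
        pos = 2000
        rc = query.reverse_complement().residues
        residues = genome.residues[:pos] + rc + genome.residues[pos + 120 :]
        genome = NucleotideSequence("g", residues)
        regions = find_candidate_regions(query, genome)
        minus = [r for r in regions if r.strand == "-"]
        assert minus
        overlaps = [max(0, min(r.end, pos + 120) - max(r.start, pos)) for r in minus]
        assert max(overlaps) >= 0.9 * 120

    def test_random_pairs_rarely_seed(self):
        # expected exact 13-mer hits per strand: (|q|-12)(|g|-12)/4^13 ~ 0.0065,
        # so ~0.4 expected over 30 pairs and two strands
        rng = np.random.default_rng(23)
        total = 0
        for i in range(30):
            q = random_sequence(rng, 100, f"q{i}")
            g = random_sequence(rng, 5000, f"g{i}")
            total += len(find_candidate_regions(q, g, k=13, min_score=13))
        assert total <= 5

    def test_overlapping_regions_are_merged(self):
        rng = np.random.default_rng(24)
        query = random_sequence(rng, 150, "q")
        genome_res = random_sequence(rng, 3000, "g").residues
        genome = NucleotideSequence(
            "g", genome_res[:500] + query.residues + genome_res[650:]
        )
        single = find_candidate_regions(query, genome, sweep=[(1, -2)])
        doubled = find_candidate_regions(query, genome, sweep=[(1, -2), (1, -2)])
        assert [(r.start, r.end, r.strand) for r in doubled] == [
            (r.start, r.end, r.strand) for r in single
        ]

    def test_empty_sweep_rejected(self):
        rng = np.random.default_rng(25)
        with pytest.raises(ValueError):
            find_candidate_regions(
                random_sequence(rng, 50, "q"), random_sequence(rng, 500, "g"), sweep=[]
            )


class TestExtendToGlobal:
    def _planted(self, seed, qlen=200, strand="+"):
        rng = np.random.default_rng(seed)
        query = random_sequence(rng, qlen, "q")
        genome = random_sequence(rng, 4000, "g")
        insert = query.residues if strand == "+" else query.reverse_complement().residues
        pos = 1500
        genome = NucleotideSequence(
            "g", genome.residues[:pos] + insert + genome.residues[pos + qlen :]
        )
        return query, genome, pos

    def test_exact_plant_scores_all_match(self, small_scheme):
        query, genome, pos = self._planted(31)
        region = CandidateRegion("g", pos, pos + 200, "+", 100.0)
        _, f = extend_to_global(query, genome, region, small_scheme)
        assert f == 200 * small_scheme.match_score

    def test_minus_strand_plant_scores_like_plus(self, small_scheme):
        query, genome, pos = self._planted(32, strand="-")
        region = CandidateRegion("g", pos, pos + 200, "-", 100.0)
        _, f = extend_to_global(query, genome, region, small_scheme)
        assert f == 200 * small_scheme.match_score

    def test_window_score_matches_oracle_for_short_query(self, small_scheme):
        rng = np.random.default_rng(33)
        query = random_sequence(rng, 8, "q")
        genome = random_sequence(rng, 300, "g")
        region = CandidateRegion("g", 100, 108, "+", 10.0)
        window, f = extend_to_global(query, genome, region, small_scheme)
        assert len(window) == 8
        assert f == nw_oracle(query.residues, window.residues, small_scheme)

    def test_out_of_bounds_region_rejected(self, small_scheme):
        rng = np.random.default_rng(34)
        query = random_sequence(rng, 50, "q")
        genome = random_sequence(rng, 100, "g")
        with pytest.raises(ValueError):
            extend_to_global(
                query, genome, CandidateRegion("g", 80, 150, "+", 1.0), small_scheme
            )


class TestShuffles:
    def test_single_symbol_sequence_is_invariant(self):
        seq = NucleotideSequence("a", "AAAA")
        assert shuffle_sequence(seq, 0).residues == "AAAA"

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(s=st.text(alphabet="ACGTN", min_size=1, max_size=60), seed=st.integers(0, 100))
    def test_shuffle_preserves_base_composition(self, s, seed):
        seq = NucleotideSequence("a", s)
        out = shuffle_sequence(seq, seed)
        assert out.base_counts() == seq.base_counts()

    def test_same_seed_reproduces_shuffle(self):
        rng = np.random.default_rng(7)
        seq = random_sequence(rng, 100, "a")
        assert shuffle_sequence(seq, 123).residues == shuffle_sequence(seq, 123).residues

    def test_triplet_shuffle_of_periodic_sequence_is_identity(self):
        seq = NucleotideSequence("a", "ACGACG")
        assert shuffle_preserving_triplet_periodicity(seq, 0).residues == "ACGACG"

    def test_triplet_shuffle_output_is_a_legal_codon_class_permutation(self):
        seq = NucleotideSequence("a", "AAACCC")
        legal = {
            "".join([p0[0], p1[0], p2[0], p0[1], p1[1], p2[1]])
            for p0 in ("AC", "CA")
            for p1 in ("AC", "CA")
            for p2 in ("AC", "CA")
        }
        seen = {
            shuffle_preserving_triplet_periodicity(seq, s).residues for s in range(40)
        }
        assert seen <= legal
        assert len(seen) > 1  # the shuffle actually moves bases

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(s=st.text(alphabet="ACGT", min_size=3, max_size=60), seed=st.integers(0, 100))
    def test_triplet_shuffle_preserves_per_codon_position_composition(self, s, seed):
        seq = NucleotideSequence("a", s)
        out = shuffle_preserving_triplet_periodicity(seq, seed)
        n_full = 3 * (len(s) // 3)
        for offset in range(3):
            assert sorted(s[offset:n_full:3]) == sorted(out.residues[offset:n_full:3])
        assert s[n_full:] == out.residues[n_full:]  # trailing bases stay put


class TestZScore:
    def test_direct_arithmetic(self):
        assert z_score(120, 100, 25) == pytest.approx(4.0)

    def test_score_at_null_mean_is_zero(self):
        assert z_score(100.0, 100.0, 7.0) == 0.0

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateNullError):
            z_score(10.0, 5.0, 0.0)


class TestMonteCarlo:
    def test_self_alignment_is_highly_significant(self):
        rng = np.random.default_rng(51)
        seq = random_sequence(rng, 250, "q")
        sig = monte_carlo_significance(seq, seq, n_shuffles=60, rng=1)
        assert sig.Z >= 5.0
        assert sig.F == 250 * 2  # all-match under the default scheme
        assert sig.D > 0 and sig.n_shuffles == 60

    def test_single_shuffle_rejected(self):
        rng = np.random.default_rng(52)
        seq = random_sequence(rng, 50, "q")
        with pytest.raises(ValueError):
            monte_carlo_significance(seq, seq, n_shuffles=1, rng=0)

    def test_fixed_seed_reproduces_significance(self):
        rng = np.random.default_rng(53)
        q = random_sequence(rng, 120, "q")
        w = random_sequence(rng, 120, "w")
        a = monte_carlo_significance(q, w, n_shuffles=50, rng=99)
        b = monte_carlo_significance(q, w, n_shuffles=50, rng=99)
        assert (a.F, a.M, a.D, a.Z) == (b.F, b.M, b.D, b.Z)
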