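import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import identity_of, pairs_oracle, sw_oracle

from herv_nahr.annotation_io import GenomeSource, HervElement, SegDup, join_fragments
from herv_nahr.pair_finder import (
    AlignmentResult,
    ScoringScheme,
    alignment_identity,
    align_pair,
    enumerate_candidate_pairs,
    exclude_lcr_overlapping_pairs,
    filter_elements_by_length,
    filter_pairs,
    find_pairs,
    local_align,
    reverse_complement,
)
from herv_nahr.synthetic_data import (
    PlantedPairSpec,
    SimulationConfig,
    make_element_pair,
    make_genome,
    random_sequence,
)


def _elem(chrom="chr1", start=0, end=5000, strand="+", name="HERVH-int", join_id=0):
    return HervElement(chrom=chrom, start=start, end=end, strand=strand, name=name, join_id=join_id)


def _seqs(rng, n, length=60):
    return [random_sequence(length, rng) for _ in range(n)]


class TestLengthFilter:
    def test_boundary_kept(self):
        assert filter_elements_by_length([_elem(end=4000)]) == [_elem(end=4000)]

    def test_below_boundary_dropped(self):
        assert filter_elements_by_length([_elem(end=3999)]) == []

    def test_random_matches_brute_force(self, rng):
        elems = [
            _elem(start=0, end=int(rng.integers(1, 10_000)), join_id=i) for i in range(50)
        ]
        expected = [e for e in elems if e.length >= 4000]
        assert filter_elements_by_length(elems) == expected


class TestEnumerate:
    def test_same_strand_candidate(self):
        a, b = _elem(end=5000), _elem(start=55_000, end=60_000, join_id=1)
        assert enumerate_candidate_pairs([a, b]) == [(a, b)]

    def test_opposite_strand_excluded(self):
        a = _elem(end=5000)
        b = _elem(start=55_000, end=60_000, strand="-", join_id=1)
        assert enumerate_candidate_pairs([a, b]) == []

    def test_separation_bounds(self):
        a = _elem(end=5000)
        near = _elem(start=5000 + 9_999, end=22_000, join_id=1)
        assert enumerate_candidate_pairs([a, near]) == []
        far = _elem(start=5000 + 10_000_001, end=20_030_000, join_id=2)
        assert enumerate_candidate_pairs([a, far]) == []

    def test_overlapping_never_paired(self):
        a, b = _elem(end=5000), _elem(start=4000, end=9500, join_id=1)
        assert enumerate_candidate_pairs([a, b], min_sep=-10_000) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_random_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        elems = []
        for i in range(10):
            start = int(rng.integers(0, 2_000_000))
            elems.append(
                _elem(
                    chrom=f"chr{rng.integers(1, 3)}",
                    start=start,
                    end=start + int(rng.integers(4000, 8000)),
                    strand="+-"[rng.integers(0, 2)],
                    join_id=i,
                )
            )
        got = {
            ((a.chrom, a.start, a.end), (b.chrom, b.start, b.end))
            for a, b in enumerate_candidate_pairs(elems, 10_000, 1_000_000)
        }
        assert got == pairs_oracle(elems, 10_000, 1_000_000)


class TestLocalAlign:
    def test_identical(self):
        aln = local_align("ACGT", "ACGT")
        assert aln.identity == 1.0 and aln.aln_length == 4 and aln.score == 4

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_example_matches_dp_oracle(self):
        scoring = ScoringScheme(match=1, mismatch=-1)
        aln = local_align("ACGTACGT", "ACGAACGT", scoring)
        score, ga, gb, *_ = sw_oracle("ACGTACGT", "ACGAACGT", 1, -1, -10, -25)
        assert aln.score == score
        assert (aln.aligned_a, aln.aligned_b) == (ga, gb)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_pairs_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_sequence(int(rng.integers(20, 200)), rng)
        b = random_sequence(int(rng.integers(20, 200)), rng)
        aln = local_align(a, b)
        score, ga, gb, a0, b0 = sw_oracle(a, b)
        assert aln.score == score
        assert (aln.aligned_a, aln.aligned_b) == (ga, gb)
        assert (aln.a_start, aln.b_start) == (a0, b0)
        assert aln.identity == pytest.approx(identity_of(ga, gb))

    def test_score_agrees_with_biopython(self):
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner(mode="local")
        m = substitution_matrices.Array("ACGTN", dims=2)
        for x in "ACGTN":
            for y in "ACGTN":
                m[x, y] = 1.0 if (x == y and x != "N") else -1.0
        aligner.substitution_matrix = m
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -25
        rng = np.random.default_rng(123)
        for _ in range(10):
            a = random_sequence(150, rng)
            b = random_sequence(150, rng)
            assert local_align(a, b).score == int(aligner.score(a, b))

    def test_planted_divergence_identity(self, small_blueprint):
        seq_a, seq_b, realized, _ = make_element_pair(small_blueprint, 0.05, seed=2)
        aln = local_align(seq_a, seq_b)
        assert abs(aln.identity - realized) <= 0.005

    def test_n_mismatches_everything(self):
        aln = local_align("ACNGT", "ACNGT")
        assert aln.score < 5

    @given(st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_score_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = random_sequence(int(rng.integers(10, 80)), rng)
        b = random_sequence(int(rng.integers(10, 80)), rng)
        assert local_align(a, b).score == local_align(b, a).score

    @given(st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_identity_symmetric_for_homologs(self, seed):
        # swapping the inputs must not change identity/length where the
        # optimum is unique (homologous sequences, the screening use case)
        rng = np.random.default_rng(seed)
        a = random_sequence(int(rng.integers(60, 150)), rng)
        b = list(a)
        for p in rng.choice(len(a), size=max(1, len(a) // 20), replace=False):
            b[p] = "ACGT"[(("ACGT".index(b[p])) + 1) % 4]
        b = "".join(b)
        f, r = local_align(a, b), local_align(b, a)
        assert f.score == r.score
        assert f.identity == pytest.approx(r.identity)
        assert f.aln_length == r.aln_length


class TestAlignmentIdentity:
    def _aln(self, ga, gb):
        return AlignmentResult(
            aligned_a=ga, aligned_b=gb, a_start=0, a_end=len(ga.replace("-", "")),
            b_start=0, b_end=len(gb.replace("-", "")), score=0,
            identity=identity_of(ga, gb), aln_length=len(ga),
        )

    def test_98_of_100(self):
        ga = "A" * 100
        gb = "A" * 98 + "CC"
        assert alignment_identity(self._aln(ga, gb)) == 0.98

    def test_94_boundary_passes_threshold(self):
        ga = "A" * 100
        gb = "A" * 94 + "C" * 6
        aln = self._aln(ga, gb)
        assert alignment_identity(aln) == 0.94
        assert aln.identity >= 0.94

    def test_hand_count_with_gaps(self):
        # 100 columns: 2 substitutions + 3 single-base gap columns -> 95/100
        ga = "A" * 40 + "-" + "A" * 30 + "--" + "A" * 27
        gb = "A" * 20 + "C" + "A" * 19 + "G" + "A" * 30 + "GG" + "A" * 26 + "T"
        aln = self._aln(ga, gb)
        assert aln.aln_length == 100
        assert alignment_identity(aln) == pytest.approx(0.95)

    def test_gap_excluded_mode(self):
        ga = "AAAA-AAAA"
        gb = "AAAACAAAA"
        aln = self._aln(ga, gb)
        assert alignment_identity(aln, count_gaps=True) == pytest.approx(8 / 9)
        assert alignment_identity(aln, count_gaps=False) == pytest.approx(1.0)


class TestFilterPairs:
    def _pair(self, identity, aln_length):
        ga = "A" * aln_length
        aln = AlignmentResult(
            aligned_a=ga, aligned_b=ga, a_start=0, a_end=aln_length,
            b_start=0, b_end=aln_length, score=aln_length,
            identity=identity, aln_length=aln_length,
        )
        from herv_nahr.pair_finder import HervPair

        return HervPair(
            elem_a=_elem(end=aln_length + 1),
            elem_b=_elem(start=100_000, end=100_000 + aln_length + 1, join_id=1),
            alignment=aln,
        )

    def test_kept(self):
        assert filter_pairs([self._pair(0.95, 2500)]) != []

    def test_ltr_only_alignment_dropped(self):
        assert filter_pairs([self._pair(0.95, 450)]) == []

    def test_boundaries_inclusive(self):
        assert filter_pairs([self._pair(0.94, 2000)]) != []
        assert filter_pairs([self._pair(0.9399, 2000)]) == []

    def test_threshold_sweep_matches_brute_force(self, rng):
        pairs = [
            self._pair(float(rng.uniform(0.85, 1.0)), int(rng.integers(500, 4000)))
            for _ in range(50)
        ]
        for min_id, min_len in ((0.9, 1000), (0.94, 2000), (0.97, 3000)):
            got = filter_pairs(pairs, min_id, min_len)
            expected = [
                p
                for p in pairs
                if p.alignment.identity >= min_id and p.alignment.aln_length >= min_len
            ]
            assert got == expected

    def test_monotone_in_thresholds(self, rng):
        pairs = [
            self._pair(float(rng.uniform(0.9, 1.0)), int(rng.integers(1000, 4000)))
            for _ in range(30)
        ]
        base = set(map(id, filter_pairs(pairs, 0.92, 1500)))
        stricter = set(map(id, filter_pairs(pairs, 0.95, 2500)))
        assert stricter <= base


class TestLcrExclusion:
    def _pair(self):
        from herv_nahr.pair_finder import HervPair

        ga = "A" * 2500
        aln = AlignmentResult(
            aligned_a=ga, aligned_b=ga, a_start=0, a_end=2500, b_start=0,
            b_end=2500, score=2500, identity=0.99, aln_length=2500,
        )
        return HervPair(
            elem_a=_elem(start=10_000, end=16_000),
            elem_b=_elem(start=60_000, end=66_000, join_id=1),
            alignment=aln,
        )

    def test_qualifying_overlap_dropped(self):
        sd = SegDup("chr1", 12_000, 13_000, "chr1", 100_000, 101_000, "+", 0.97)
        assert exclude_lcr_overlapping_pairs([self._pair()], [sd]) == []

    def test_inverted_orientation_kept(self):
        sd = SegDup("chr1", 12_000, 13_000, "chr1", 100_000, 101_000, "-", 0.97)
        assert exclude_lcr_overlapping_pairs([self._pair()], [sd]) != []

    def test_low_identity_kept(self):
        sd = SegDup("chr1", 12_000, 13_000, "chr1", 100_000, 101_000, "+", 0.92)
        assert exclude_lcr_overlapping_pairs([self._pair()], [sd]) != []

    def test_interchromosomal_segdup_ignored(self):
        sd = SegDup("chr1", 12_000, 13_000, "chr9", 100_000, 101_000, "+", 0.97)
        assert exclude_lcr_overlapping_pairs([self._pair()], [sd]) != []

    def test_too_close_copies_ignored(self):
        sd = SegDup("chr1", 12_000, 13_000, "chr1", 14_000, 15_000, "+", 0.97)
        assert exclude_lcr_overlapping_pairs([self._pair()], [sd]) != []

    @pytest.mark.parametrize("seed", range(3))
    def test_random_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pair = self._pair()
        segdups = []
        for _ in range(40):
            s1 = int(rng.integers(0, 120_000))
            s2 = int(rng.integers(0, 500_000))
            segdups.append(
                SegDup(
                    "chr1", s1, s1 + int(rng.integers(1000, 8000)),
                    "chr1", s2, s2 + int(rng.integers(1000, 8000)),
                    "+-"[rng.integers(0, 2)], float(rng.uniform(0.9, 1.0)),
                )
            )

        def brute(p, sds):
            for sd in sds:
                if sd.other_strand != "+" or sd.frac_match <= 0.94:
                    continue
                gap = (sd.other_start - sd.end) if sd.start <= sd.other_start else (sd.start - sd.other_end)
                if not (5000 <= gap <= 10_000_000):
                    continue
                for es, ee in ((p.elem_a.start, p.elem_a.end), (p.elem_b.start, p.elem_b.end)):
                    for cs, ce in ((sd.start, sd.end), (sd.other_start, sd.other_end)):
                        if es < ce and cs < ee:
                            return True
            return False

        survived = exclude_lcr_overlapping_pairs([pair], segdups)
        assert (survived == []) == brute(pair, segdups)


class TestRecovery:
    def test_95_recovered_90_rejected(self):
        cfg = SimulationConfig(
            seed=21,
            pairs=(PlantedPairSpec(0.05), PlantedPairSpec(0.10, qualifies=False)),
        )
        genome, anns, truth = make_genome(cfg)
        pairs = find_pairs(join_fragments(anns), genome)
        assert len(pairs) == 1
        rec = truth.pairs[0]
        assert (pairs[0].elem_a.start, pairs[0].elem_a.end) == (rec["a_start"], rec["a_end"])

    def test_minus_strand_pair_recovered(self):
        cfg = SimulationConfig(seed=22, pairs=(PlantedPairSpec(0.02, strand="-"),))
        genome, anns, truth = make_genome(cfg)
        pairs = find_pairs(join_fragments(anns), genome)
        assert len(pairs) == 1
        assert pairs[0].elem_a.strand == "-"
        assert pairs[0].alignment.identity >= 0.97

    def test_align_pair_strand_mismatch_raises(self):
        genome = GenomeSource({"chr1": "ACGT" * 100})
        with pytest.raises(ValueError):
            align_pair(
                _elem(end=100), _elem(start=200, end=300, strand="-", join_id=1), genome
            )


def test_reverse_complement():
    assert reverse_complement("ACGTN") == "NACGT"
    assert reverse_complement(reverse_complement("GATTACA")) == "GATTACA"


def test_scoring_scheme_validation():
    with pytest.raises(ValueError):
        ScoringScheme(match=0)
    with pytest.raises(ValueError):
        ScoringScheme(gap_extend=5)
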