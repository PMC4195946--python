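import numpy as np
import pytest

from herv_nahr.breakpoint_mapper import (
    BreakpointCall,
    JunctionMappingError,
    cnv_size,
    find_cis_morphisms,
    format_size,
    load_confirmed_breakpoints,
    map_junction,
    read_breakpoint_table,
    uncertainty_widths,
    windowed_identity,
    write_breakpoint_table,
)
from herv_nahr.pair_finder import AlignmentResult, local_align
from herv_nahr.synthetic_data import make_element_pair, make_junction


def _aln(ga, gb):
    ident = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return AlignmentResult(
        aligned_a=ga, aligned_b=gb, a_start=0, a_end=len(ga.replace("-", "")),
        b_start=0, b_end=len(gb.replace("-", "")), score=0,
        identity=ident / len(ga), aln_length=len(ga),
    )


class TestCisMorphisms:
    def test_identical_sequences_empty(self):
        assert find_cis_morphisms(local_align("ACGTACGT", "ACGTACGT")) == []

    def test_single_substitution(self):
        cis = find_cis_morphisms(_aln("ACGT", "AGGT"))
        assert len(cis) == 1
        cm = cis[0]
        assert cm.column == 1 and cm.kind == "substitution"
        assert (cm.base_a, cm.base_b) == ("C", "G")
        assert (cm.pos_a, cm.pos_b) == (1, 1)

    def test_indel_run_counted_once(self):
        cis = find_cis_morphisms(_aln("AAAATTTAAAA", "AAAA---AAAA"))
        assert len(cis) == 1
        cm = cis[0]
        assert cm.kind == "insertion_in_a"
        assert cm.base_a == "TTT"
        assert cm.pos_a == 4 and cm.pos_b == 4

    def test_gap_in_a(self):
        cis = find_cis_morphisms(_aln("AAAA--AAAA", "AAAACCAAAA"))
        (cm,) = cis
        assert cm.kind == "insertion_in_b" and cm.base_b == "CC"

    def test_synthetic_planted_positions_recovered(self, snv_pair):
        cis = find_cis_morphisms(snv_pair["alignment"])
        got = sorted(c.pos_a for c in cis)
        assert got == snv_pair["variants"]
        assert all(c.kind == "substitution" for c in cis)

    def test_sorted_by_column(self, diverged_pair):
        cols = [c.column for c in find_cis_morphisms(diverged_pair["alignment"])]
        assert cols == sorted(cols)


class TestMapJunction:
    def test_toy_two_variant_case(self):
        a = "A" * 10 + "C" + "A" * 39 + "G" + "A" * 10
        b = "A" * 10 + "T" + "A" * 39 + "C" + "A" * 10
        aln = _aln(a, b)
        junction = a[:30] + b[30:]
        call = map_junction(junction, aln, a, b, a_offset=0, b_offset=10_000)
        assert (call.column_lo, call.column_hi) == (10, 50)
        assert call.start_max == 11 and call.start_min == 51  # 1-based
        assert call.stop_min == 10_011 and call.stop_max == 10_051

    def test_no_crossover_raises(self):
        a = "A" * 10 + "C" + "A" * 39 + "G" + "A" * 10
        b = "A" * 10 + "T" + "A" * 39 + "C" + "A" * 10
        with pytest.raises(JunctionMappingError, match="no crossover"):
            map_junction(a, _aln(a, b), a, b, b_offset=10_000)

    def test_complex_event_raises(self):
        a = "A" * 10 + "C" + "A" * 20 + "G" + "A" * 20 + "C" + "A" * 10
        b = "A" * 10 + "T" + "A" * 20 + "T" + "A" * 20 + "G" + "A" * 10
        chimera = a[:20] + b[20:45] + a[45:]  # A -> B -> A
        with pytest.raises(JunctionMappingError, match="complex"):
            map_junction(chimera, _aln(a, b), a, b, b_offset=10_000)

    def test_identical_elements_raise(self):
        a = "ACGT" * 20
        with pytest.raises(JunctionMappingError, match="identical"):
            map_junction(a, local_align(a, a), a, a, b_offset=10_000)

    @pytest.mark.parametrize("seed", range(4))
    def test_snv_junctions_exact_recovery(self, blueprint, seed):
        seq_a, seq_b, _, _ = make_element_pair(blueprint, 0.02, seed=seed)
        aln = local_align(seq_a, seq_b)
        rng = np.random.default_rng(seed + 50)
        for _ in range(5):
            col = int(rng.integers(500, aln.aln_length - 500))
            junction, truth = make_junction(seq_a, seq_b, col, read_length=2000, alignment=aln)
            call = map_junction(junction, aln, seq_a, seq_b, a_offset=10_000, b_offset=500_000)
            assert call.column_lo == truth["flank_lo_column"]
            assert call.column_hi == truth["flank_hi_column"]

    @pytest.mark.parametrize("seed", range(4))
    def test_indel_junctions_contain_truth(self, blueprint, seed):
        seq_a, seq_b, _, _ = make_element_pair(blueprint, 0.03, seed=seed, indel_rate=0.1)
        aln = local_align(seq_a, seq_b)
        rng = np.random.default_rng(seed + 80)
        for _ in range(5):
            col = int(rng.integers(500, aln.aln_length - 500))
            junction, truth = make_junction(seq_a, seq_b, col, read_length=2000, alignment=aln)
            call = map_junction(junction, aln, seq_a, seq_b, a_offset=10_000, b_offset=500_000)
            assert call.column_lo <= col <= call.column_hi

    def test_no_informative_cis_inside_interval(self, blueprint):
        # with pure substitutions the reported bounds are adjacent
        # cis-morphisms: nothing informative lies strictly inside
        seq_a, seq_b, _, _ = make_element_pair(blueprint, 0.02, seed=9)
        aln = local_align(seq_a, seq_b)
        cis_cols = np.array([c.column for c in find_cis_morphisms(aln)])
        junction, _ = make_junction(seq_a, seq_b, 2500, read_length=2000, alignment=aln)
        call = map_junction(junction, aln, seq_a, seq_b, a_offset=10_000, b_offset=500_000)
        inside = cis_cols[(cis_cols > call.column_lo) & (cis_cols < call.column_hi)]
        assert inside.size == 0


class TestTable1Arithmetic:
    def test_patient9_proximal_uncertainty_8bp(self):
        calls = {c.sample_id: c for c in load_confirmed_breakpoints()}
        assert uncertainty_widths(calls["9"]) == (8, 8)

    def test_patient1_proximal_uncertainty_162bp(self):
        calls = {c.sample_id: c for c in load_confirmed_breakpoints()}
        assert uncertainty_widths(calls["1"])[0] == 222150567 - 222150405 == 162

    def test_all_sizes_match_printed_values(self):
        calls = {c.sample_id: c for c in load_confirmed_breakpoints()}
        expected = {
            "1": "1.05 Mb",  # 223201703 - 222150567
            "3": "1.36 Mb",  # 76804990 - 75444972
            "4": "877 kb",  # 78195410 - 77318740
            "8": "189 kb",  # 130623915 - 130434845
        }
        for patient, size in expected.items():
            assert format_size(cnv_size(calls[patient])) == size

    def test_patient4_size_bases(self):
        calls = {c.sample_id: c for c in load_confirmed_breakpoints()}
        assert cnv_size(calls["4"]) == 78195410 - 77318740 == 876_670

    def test_widths_span_8_to_162(self):
        widths = [w for c in load_confirmed_breakpoints() for w in uncertainty_widths(c)]
        assert min(widths) == 8
        assert max(widths) == 162

    def test_degenerate_zero_widths(self):
        call = BreakpointCall("x", ".", "Del", "chr1", 100, 100, 200, 200)
        assert uncertainty_widths(call) == (0, 0)
        assert cnv_size(BreakpointCall("x", ".", "Del", "chr1", 99, 100, 100, 101)) == 0


class TestFormatSize:
    @pytest.mark.parametrize(
        "bases,expected",
        [
            (1_051_136, "1.05 Mb"),
            (1_360_018, "1.36 Mb"),
            (876_670, "877 kb"),
            (189_070, "189 kb"),
            (160_000, "160 kb"),
            (999, "999 bp"),
            (4_500, "4.5 kb"),
        ],
    )
    def test_values(self, bases, expected):
        assert format_size(bases) == expected


class TestWindowedIdentity:
    def test_identical_constant_one(self):
        prof = windowed_identity(local_align("ACGT" * 50, "ACGT" * 50))
        assert np.allclose(prof, 1.0)

    def test_single_mismatch_minimum(self):
        a = "A" * 100
        b = "A" * 50 + "C" + "A" * 49
        prof = windowed_identity(_aln(a, b), window=50)
        assert prof.min() == pytest.approx(49 / 50)
        assert prof[0] == pytest.approx(1.0)

    def test_truncated_window_at_edges(self):
        a = "CAAA"
        b = "GAAA"
        prof = windowed_identity(_aln(a, b), window=50)
        # whole alignment fits in one truncated window
        assert np.allclose(prof, 3 / 4)

    def test_minima_at_planted_indel_clusters(self, blueprint):
        seq_a, seq_b, _, _ = make_element_pair(blueprint, 0.01, seed=3, indel_rate=0.5)
        aln = local_align(seq_a, seq_b)
        prof = windowed_identity(aln)
        gap_cols = [i for i, (x, y) in enumerate(zip(aln.aligned_a, aln.aligned_b)) if x == "-" or y == "-"]
        assert gap_cols, "fixture should contain indels"
        argmin = int(np.argmin(prof))
        assert min(abs(argmin - g) for g in gap_cols) <= 25

    def test_matches_brute_force(self, rng):
        a = "".join(rng.choice(list("ACGT"), 200))
        b = "".join(rng.choice(list("ACGT"), 200))
        aln = _aln(a, b)
        prof = windowed_identity(aln, window=50)
        for col in [0, 7, 100, 199]:
            lo, hi = max(0, col - 24), min(200, col + 26)
            expected = sum(1 for i in range(lo, hi) if a[i] == b[i]) / (hi - lo)
            assert prof[col] == pytest.approx(expected)


def test_breakpoint_table_round_trip(tmp_path):
    calls = load_confirmed_breakpoints()
    p = tmp_path / "bp.tsv"
    write_breakpoint_table(calls, str(p))
    got = read_breakpoint_table(str(p))
    assert [(c.sample_id, c.start_max, c.stop_max) for c in got] == [
        (c.sample_id, c.start_max, c.stop_max) for c in calls
    ]


def test_bounds_invariant_enforced():
    with pytest.raises(ValueError):
        BreakpointCall("x", ".", "Del", "chr1", 200, 100, 300, 400)
    with pytest.raises(ValueError):
        BreakpointCall("x", ".", "Del", "chr1", 100, 200, 150, 400)
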