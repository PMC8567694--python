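"""Pseudo-indel tiling, TE-indel matching, Fisher/BH machinery, RMS calls."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rmscan import (
    GenomicInterval,
    IndelRecord,
    bh_adjust,
    call_rms,
    count_matches,
    expanded_pmei_scan,
    fisher_subfamily,
    generate_pseudo_indels,
    match_te,
    pseudo_indel_arrays,
)
from rmscan.screen import IntervalMatchIndex, SubfamilyTestResult
from tests.conftest import exact_fisher_tail, make_te

CHROM_LEN = 10_000_000


def rec(start, end, indel_id="d1", chrom="chr1"):
    return IndelRecord(GenomicInterval(chrom, start, end), "DEL", "test", indel_id)


class TestPseudoIndelTiling:
    def test_even_length_tiling(self):
        # an L=100 indel needs 100 + 249*50 = 12,550 bp of left flank for a
        # full complement of 250 tiles
        tiles = generate_pseudo_indels(rec(100_000, 100_100), CHROM_LEN,
                                       n_total=500)
        assert len(tiles) == 500
        right = [t for t in tiles if t.side == "right"]
        left = [t for t in tiles if t.side == "left"]
        assert len(right) == len(left) == 250
        starts = sorted(t.interval.start for t in right)[:3]
        assert starts == [100_100, 100_150, 100_200]  # innermost flush, step 50
        assert all(t.interval.length() == 100 for t in tiles)
        # innermost left tile ends at the indel start
        assert max(t.interval.end for t in left) == 100_000

    def test_odd_length_overlap_floored(self):
        tiles = generate_pseudo_indels(rec(50_000, 50_101), CHROM_LEN, n_total=10)
        right = sorted((t.interval.start for t in tiles if t.side == "right"))
        assert right[1] - right[0] == 51  # step = L - floor(L/2)
        # adjacent same-side tiles share floor(101/2) = 50 bp
        assert (right[0] + 101) - right[1] == 50

    def test_left_boundary_clipping(self):
        tiles = generate_pseudo_indels(rec(120, 220), CHROM_LEN, n_total=500)
        left = [t for t in tiles if t.side == "left"]
        assert len(left) == 1  # floor((120-100)/50)+1
        assert (left[0].interval.start, left[0].interval.end) == (20, 120)
        assert len([t for t in tiles if t.side == "right"]) == 250

    def test_vectorised_tiling_agrees_with_reference(self):
        rng = np.random.default_rng(7)
        records = []
        for i in range(50):
            start = int(rng.integers(0, 200_000))
            length = int(rng.integers(50, 2000))
            records.append(rec(start, start + length, f"d{i}"))
        expected = sorted(
            (p.interval.start, p.interval.end)
            for r in records
            for p in generate_pseudo_indels(r, CHROM_LEN, n_total=100)
        )
        arrays = pseudo_indel_arrays(records, {"chr1": CHROM_LEN}, n_total=100)
        got = sorted(map(tuple, arrays["chr1"].tolist()))
        assert got == expected


class TestMatching:
    @pytest.mark.parametrize(
        "te_span,indel_span,expected",
        [
            ((0, 300), (0, 300), True),
            ((0, 300), (0, 269), False),  # 269/300 ~ 0.897 < 0.9
            ((0, 300), (15, 300), True),  # 285/300 = 0.95
        ],
    )
    def test_ninety_percent_mutual_boundary(self, te_span, indel_span, expected):
        te = make_te("chr1", *te_span)
        assert match_te(te, GenomicInterval("chr1", *indel_span)) is expected

    def test_count_matches_dedups_per_indel(self):
        # two TEs matching the same true indel count it once
        tes = [make_te("chr1", 1000, 1300, instance_id="a"),
               make_te("chr1", 1005, 1300, instance_id="b")]
        true_index = IntervalMatchIndex.from_records([rec(1000, 1300)])
        pseudo_index = IntervalMatchIndex({})
        assert count_matches(tes, true_index, pseudo_index) == (1, 0)

    def test_no_tes_no_matches(self):
        true_index = IntervalMatchIndex.from_records([rec(1000, 1300)])
        assert count_matches([], true_index, IntervalMatchIndex({})) == (0, 0)

    def test_index_agrees_with_brute_force(self):
        rng = np.random.default_rng(3)
        spans = []
        for _ in range(500):
            start = int(rng.integers(0, 50_000))
            spans.append([start, start + int(rng.integers(50, 600))])
        index = IntervalMatchIndex({"chr1": np.array(spans)})
        ivs = [GenomicInterval("chr1", s, e) for s, e in spans]
        for _ in range(100):
            start = int(rng.integers(0, 50_000))
            q = GenomicInterval("chr1", start, start + int(rng.integers(50, 600)))
            brute = {
                i for i, other in enumerate(ivs)
                if match_te(make_te("chr1", other.start, other.end), q)
            }
            got = set(
                index.original_indices("chr1", index.matching_positions(q)).tolist()
            )
            assert got == brute


class TestFisher:
    def test_zero_true_matches_gives_p_one(self):
        assert fisher_subfamily(0, 100, 1000, 50_000) == 1.0

    def test_small_table_matches_exact_enumeration(self):
        p = fisher_subfamily(2, 0, 10, 5000)  # table [[2,8],[0,5000]]
        oracle = float(exact_fisher_tail(2, 8, 0, 5000))
        assert p == pytest.approx(oracle, rel=1e-12)

    def test_enrichment_example_table(self):
        # 464-subfamily universe, 20 hits, 10 targets, 8 overlapping
        p = fisher_subfamily(8, 2, 20, 444)
        assert f"{p:.1e}" == "1.1e-10"

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_subfamily(5, 0, 3, 100)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 60), st.integers(0, 60),
           st.integers(0, 200), st.integers(0, 200))
    def test_random_tables_match_oracle(self, a, b, c, d):
        p = fisher_subfamily(a, c, a + b, c + d)
        oracle = float(exact_fisher_tail(a, b, c, d))
        assert p == pytest.approx(oracle, rel=1e-11, abs=1e-300)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_step_up_with_min_accumulation(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_q_dominates_p_and_is_monotone_in_rank(self, ps):
        qs = bh_adjust(ps)
        assert np.all(qs >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(qs[order]) >= -1e-12)


def result(subfamily, p):
    return SubfamilyTestResult(
        subfamily=subfamily, n_human_specific=10, avg_divergence=1.0,
        t_te=1, p_te=1, n_true=100, n_pseudo=50_000, p_value=p, log10_p=np.log10(p),
    )


class TestRmsCall:
    def test_threshold_inclusive(self):
        results = call_rms([result("A", 0.001), result("B", 0.0011)],
                           q_threshold=0.001)
        # single-comparison BH leaves p unchanged only with m=1; here m=2:
        # q_A = min(0.001*2/1, 0.0011*2/2 accumulated) -> check flags directly
        flags = {r.subfamily: r.is_rms for r in results}
        qs = {r.subfamily: r.q_value for r in results}
        assert flags == {s: qs[s] <= 0.001 for s in qs}

    def test_empty_results(self):
        assert call_rms([]) == []

    def test_fold_enrichment_degenerate_cases(self):
        r = result("A", 0.5)
        r.p_te = 0
        assert r.expected_matches == 0
        assert r.fold_enrichment == float("inf")
        r2 = result("B", 1.0)
        r2.t_te = 0
        r2.p_te = 0
        assert np.isnan(r2.fold_enrichment)


class TestExpandedScan:
    def setup_method(self):
        self.rms_te = make_te("chr1", 1000, 1300, subfamily="AluYa5",
                              instance_id="rms_te")
        self.other_te = make_te("chr1", 5000, 5300, subfamily="AluSx",
                                instance_id="old_te")
        self.retained = [rec(5000, 5300, "kept")]
        self.discarded = [rec(1000, 1300, "dup")]

    def test_discarded_match_included(self):
        out = expanded_pmei_scan(["AluYa5"], [self.rms_te, self.other_te],
                                 self.retained, self.discarded)
        assert [te.instance_id for te in out] == ["rms_te"]

    def test_non_rms_te_excluded(self):
        out = expanded_pmei_scan(["AluYa5"], [self.other_te],
                                 self.retained, self.discarded)
        assert out == []

    def test_te_matching_both_pools_appears_once(self):
        out = expanded_pmei_scan(
            ["AluYa5"], [self.rms_te],
            [rec(1001, 1300, "kept2")], self.discarded,
        )
        assert len(out) == 1
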