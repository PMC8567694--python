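"""Tile merging, count-calibrated DHS prediction and fraction matrices."""
import numpy as np
import pandas as pd
import pytest

from rmscan import (
    GenomicInterval,
    TileScore,
    hypersensitive_fraction,
    merge_and_trim,
    specificity_matrix,
    threshold_to_count,
    tile_genome,
)
from rmscan.chromatin import ancient_subfamily_reference
from tests.conftest import make_te


def tile(start, score, chrom="chr1", width=151):
    return TileScore(GenomicInterval(chrom, start, start + width), score)


class TestTiling:
    def test_step_and_tail_drop(self):
        tiles = tile_genome({"chr1": 301})
        spans = [(t.start, t.end) for t in tiles]
        assert spans == [(0, 151), (75, 226), (150, 301)]

    def test_chrom_shorter_than_width(self):
        assert tile_genome({"chr1": 150}) == []

    def test_consecutive_tiles_share_76bp(self):
        tiles = tile_genome({"chr1": 10_000})
        a, b = tiles[0], tiles[1]
        assert a.end - b.start == 76

    def test_width_must_exceed_overlap(self):
        with pytest.raises(ValueError):
            tile_genome({"chr1": 1000}, width=50, overlap=60)


class TestMergeAndTrim:
    def test_isolated_tile_kept_verbatim(self):
        (region,) = merge_and_trim([tile(1000, 2.5)])
        assert (region.interval.start, region.interval.end) == (1000, 1151)
        assert region.score == 2.5

    def test_run_of_seven_tiles_trimmed_to_centre(self):
        run = [tile(1000 + 75 * k, 1.0 + 0.1 * k) for k in range(7)]
        (region,) = merge_and_trim(run)
        # 6*75 + 151 = 601 bp span, trimmed symmetrically to 151
        assert (region.interval.start, region.interval.end) == (1225, 1376)
        assert region.score == pytest.approx(1.6)

    def test_below_threshold_excluded(self):
        assert merge_and_trim([tile(1000, 0.99)]) == []

    def test_span_cap_starts_new_region(self):
        run = [tile(1000 + 75 * k, 1.0) for k in range(10)]
        regions = merge_and_trim(run)
        assert len(regions) == 2
        assert all(r.interval.length() == 151 for r in regions)

    def test_odd_excess_trims_extra_bp_from_right(self):
        # two overlapping tiles, span 226, excess 75: trim 37 left, 38 right
        regions = merge_and_trim([tile(0, 1.0), tile(75, 1.0)])
        assert (regions[0].interval.start, regions[0].interval.end) == (37, 188)

    def test_gap_separates_regions(self):
        regions = merge_and_trim([tile(0, 1.0), tile(5_000, 1.0)])
        assert len(regions) == 2

    def test_merged_spans_never_exceed_cap(self):
        rng = np.random.default_rng(0)
        tiles = [tile(75 * k, float(s))
                 for k, s in enumerate(rng.uniform(0, 3, size=400))]
        for pre_trim_cap in [601]:
            regions = merge_and_trim(tiles, max_span=pre_trim_cap)
            assert all(r.interval.length() == 151 for r in regions)


class TestThresholdToCount:
    REGIONS = merge_and_trim(
        [tile(2000 * k, 1.0 + k * 0.5) for k in range(10)]
    )

    def test_top_n_by_score(self):
        top = threshold_to_count(self.REGIONS, 3)
        assert len(top) == 3
        assert [r.score for r in top] == sorted(
            (r.score for r in self.REGIONS), reverse=True)[:3]

    def test_more_requested_than_available(self):
        assert len(threshold_to_count(self.REGIONS, 99)) == len(self.REGIONS)

    def test_tie_at_cut_broken_lexicographically(self):
        tied = merge_and_trim([tile(9_000, 1.0), tile(3_000, 1.0)])
        (kept,) = threshold_to_count(tied, 1)
        assert kept.interval.start == 3_000

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            threshold_to_count(self.REGIONS, -1)


class TestFractions:
    def dhs(self, start, end):
        return GenomicInterval("chr1", start, end)

    def test_half_hypersensitive(self):
        tes = [make_te("chr1", 1000 * i, 1000 * i + 300, instance_id=f"t{i}")
               for i in range(4)]
        dhs = [self.dhs(950, 1150), self.dhs(2050, 2250)]
        assert hypersensitive_fraction(tes, dhs) == 0.5

    def test_49bp_overlap_not_counted(self):
        te = make_te("chr1", 1000, 1300)
        assert hypersensitive_fraction([te], [self.dhs(1251, 1500)]) == 0.0
        assert hypersensitive_fraction([te], [self.dhs(1250, 1500)]) == 1.0

    def test_empty_dhs_zero(self):
        assert hypersensitive_fraction([make_te("chr1", 0, 300)], []) == 0.0

    def test_empty_subfamily_undefined(self):
        assert np.isnan(hypersensitive_fraction([], [self.dhs(0, 200)]))


class TestSpecificityMatrix:
    def test_largest_and_fold(self):
        m = specificity_matrix(pd.DataFrame({"c1": [0.1], "c2": [0.3]},
                                            index=["AluYa5"]))
        assert m.loc["AluYa5", "largest_fraction"] == pytest.approx(0.3)
        assert m.loc["AluYa5", "fold:c1"] == pytest.approx(0.5)
        assert m.loc["AluYa5", "fold:c2"] == pytest.approx(1.5)

    def test_constant_row_all_folds_one(self):
        m = specificity_matrix(pd.DataFrame({"c1": [0.2], "c2": [0.2]},
                                            index=["s"]))
        assert m.loc["s", "fold:c1"] == m.loc["s", "fold:c2"] == 1.0

    def test_zero_row_fold_missing(self):
        m = specificity_matrix(pd.DataFrame({"c1": [0.0], "c2": [0.0]},
                                            index=["s"]))
        assert np.isnan(m.loc["s", "fold:c1"])

    def test_fold_rows_average_to_one(self):
        rng = np.random.default_rng(5)
        frac = pd.DataFrame(rng.uniform(0.01, 0.9, size=(6, 8)),
                            columns=[f"c{i}" for i in range(8)])
        m = specificity_matrix(frac)
        folds = m[[f"fold:c{i}" for i in range(8)]]
        assert np.allclose(folds.mean(axis=1), 1.0)


def test_ancient_reference_thresholds():
    tes = (
        [make_te("chr1", 10_000 + i * 400, 10_000 + i * 400 + 300,
                 subfamily="old", divergence=25.0, instance_id=f"o{i}")
         for i in range(1000)]
        + [make_te("chr1", 5_000_000 + i * 400, 5_000_000 + i * 400 + 300,
                   subfamily="young", divergence=1.0, instance_id=f"y{i}")
           for i in range(1000)]
        + [make_te("chr1", 8_000_000, 8_000_300, subfamily="rare",
                   divergence=30.0)]
    )
    assert ancient_subfamily_reference(tes) == ["old"]
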