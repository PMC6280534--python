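import math

import numpy as np
import pandas as pd
import pytest

from dmrscan.dmr import (
    DmrParams,
    _window_starts,
    call_dmcs,
    call_dmr_pipeline,
    filter_dmrs,
    merge_and_shrink,
    rank_dmrs,
    robust_index,
    scan_windows,
    write_dmrs_bed,
    write_dmrs_tsv,
)
from dmrscan.methylome import filter_by_depth, pool_replicates
from conftest import make_table


class TestWindowTiling:
    def test_length_400(self):
        starts = _window_starts(400, 200, 50)
        assert starts.tolist() == [0, 50, 100, 150, 200]

    def test_unaligned_tail_gets_final_window(self):
        starts = _window_starts(430, 200, 50)
        assert starts[-1] == 230
        assert starts[:-1].tolist() == [0, 50, 100, 150, 200]

    def test_short_contig_single_window(self):
        assert _window_starts(150, 200, 50).tolist() == [0]


def _two_conditions(rows_a, rows_b):
    ta = make_table(rows_a, sample="a1", condition="A")
    tb = make_table(rows_b, sample="b1", condition="B")
    return ta, tb


class TestScanWindows:
    def test_balanced_window_never_candidate(self):
        rows_a = [("chr1", 10, "+", "CG", 5, 10)]
        rows_b = [("chr1", 10, "+", "CG", 5, 10)]
        ta, tb = _two_conditions(rows_a, rows_b)
        mask = filter_by_depth([ta, tb], 4)
        w = scan_windows(ta, tb, mask, chrom_sizes={"chr1": 400})
        assert (w["p_value"] == 1.0).all()
        assert (w["fdr"] >= 1.0 - 1e-12).all()

    def test_uncovered_windows_not_tested(self):
        rows = [("chr1", 10, "+", "CG", 5, 10)]
        ta, tb = _two_conditions(rows, rows)
        mask = filter_by_depth([ta, tb], 4)
        w = scan_windows(ta, tb, mask, chrom_sizes={"chr1": 1000})
        # position 9 (0-based) lies in the single first window only
        assert set(w["start"]) == {0}

    def test_counts_pool_over_contained_cytosines(self):
        rows_a = [("chr1", 10, "+", "CG", 3, 10), ("chr1", 20, "+", "CG", 2, 10)]
        rows_b = [("chr1", 10, "+", "CG", 1, 10), ("chr1", 20, "+", "CG", 0, 10)]
        ta, tb = _two_conditions(rows_a, rows_b)
        mask = filter_by_depth([ta, tb], 4)
        w = scan_windows(ta, tb, mask, chrom_sizes={"chr1": 200})
        row = w.iloc[0]
        assert (row["meth_a"], row["unmeth_a"]) == (5, 15)
        assert (row["meth_b"], row["unmeth_b"]) == (1, 19)
        assert row["n_sites"] == 2


class TestCallDmcs:
    def test_strong_difference_is_dmc(self):
        ta, tb = _two_conditions(
            [("chr1", 10, "+", "CG", 10, 10)], [("chr1", 10, "+", "CG", 0, 10)])
        mask = filter_by_depth([ta, tb], 4)
        dmcs = call_dmcs(ta, tb, mask)
        assert len(dmcs) == 1
        assert dmcs.loc[0, "p_value"] == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_balanced_not_dmc(self):
        ta, tb = _two_conditions(
            [("chr1", 10, "+", "CG", 5, 10)], [("chr1", 10, "+", "CG", 5, 10)])
        mask = filter_by_depth([ta, tb], 4)
        assert len(call_dmcs(ta, tb, mask)) == 0

    def test_depth_mask_blocks_dmc(self):
        # same strong signal, but one library at depth 3 fails the mask
        ta = make_table([("chr1", 10, "+", "CG", 10, 10)], condition="A")
        tb = make_table([("chr1", 10, "+", "CG", 0, 10)], condition="B")
        shallow = make_table([("chr1", 10, "+", "CG", 1, 3)], condition="A")
        mask = filter_by_depth([ta, shallow, tb], 4)
        assert len(call_dmcs(ta, tb, mask)) == 0

    def test_region_restriction(self):
        rows_a = [("chr1", 10, "+", "CG", 10, 10), ("chr1", 500, "+", "CG", 10, 10)]
        rows_b = [("chr1", 10, "+", "CG", 0, 10), ("chr1", 500, "+", "CG", 0, 10)]
        ta, tb = _two_conditions(rows_a, rows_b)
        mask = filter_by_depth([ta, tb], 4)
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        dmcs = call_dmcs(ta, tb, mask, regions=regions)
        assert list(dmcs["pos"]) == [10]


class TestMergeAndShrink:
    def _cand(self, spans, fdr=0.01):
        return pd.DataFrame([
            {"chrom": "chr1", "start": s, "end": e, "context": "CG", "fdr": fdr}
            for s, e in spans])

    def _dmcs(self, positions):
        return pd.DataFrame({
            "chrom": "chr1", "pos": positions, "strand": "+",
            "context": "CG", "level_a": 0.9, "level_b": 0.1, "p_value": 0.001})

    def test_overlapping_windows_merge(self):
        out = merge_and_shrink(self._cand([(100, 300), (250, 450)]),
                               self._dmcs([101, 449]))
        assert len(out) == 1
        assert out.loc[0, "start"] == 100 and out.loc[0, "end"] == 449

    def test_shrink_to_first_last_dmc(self):
        # merged region [100, 450) with DMCs at 0-based 120 and 430
        out = merge_and_shrink(self._cand([(100, 300), (250, 450)]),
                               self._dmcs([121, 431]))
        assert out.loc[0, "start"] == 120
        assert out.loc[0, "end"] == 431  # half-open end = last DMC + 1
        assert out.loc[0, "n_dmc"] == 2

    def test_region_without_dmc_dropped(self):
        out = merge_and_shrink(self._cand([(100, 300)]), self._dmcs([1000]))
        assert out.empty

    def test_bookended_merge_but_gap_does_not(self):
        out = merge_and_shrink(self._cand([(0, 200), (200, 400), (401, 601)]),
                               self._dmcs([10, 390, 450]))
        assert len(out) == 2


class TestFilterDmrs:
    def _regions(self, n_dmc, diff):
        return pd.DataFrame({
            "chrom": ["chr1"], "start": [0], "end": [100],
            "n_dmc": [n_dmc], "fdr": [0.01], "mean_diff": [diff]})

    def test_too_few_dmcs_rejected(self):
        assert filter_dmrs(self._regions(3, -0.4)).empty

    def test_small_difference_rejected(self):
        assert filter_dmrs(self._regions(8, -0.10)).empty

    def test_passing_region_is_hypo(self):
        out = filter_dmrs(self._regions(5, -0.30))
        assert len(out) == 1
        assert out.loc[0, "direction"] == "hypo"

    def test_positive_diff_is_hyper(self):
        out = filter_dmrs(self._regions(5, 0.30))
        assert out.loc[0, "direction"] == "hyper"

    def test_boundary_values_excluded(self):
        # n_dmc > 3 and |diff| > 0.15 are strict on the diff side
        assert filter_dmrs(self._regions(4, -0.15)).empty
        assert len(filter_dmrs(self._regions(4, -0.1501))) == 1


class TestRobustIndex:
    def test_identical_replicates_zero(self):
        # FC1 = FC2 = 0.5 given levels (a, b) chosen accordingly
        assert robust_index([0.99, 0.99], [0.49, 0.49]) == pytest.approx(0.0)

    def test_direct_formula(self):
        # log2FC = (-2, -1): levels a=(0.79, 0.39), b with epsilon=0.01
        # pick levels so (b + eps)/(a + eps) = 0.25 and 0.5 exactly
        a1, a2 = 0.79, 0.39
        b1 = 0.25 * (a1 + 0.01) - 0.01
        b2 = 0.5 * (a2 + 0.01) - 0.01
        assert robust_index([a1, a2], [b1, b2]) == pytest.approx(1 / 3, rel=1e-9)

    def test_opposite_signs_na(self):
        # log2FC = (+1, -1): denominator zero
        a1, b1 = 0.24, 0.49  # FC1 = 2
        a2, b2 = 0.49, 0.24  # FC2 = 0.5
        assert math.isnan(robust_index([a1, a2], [b1, b2]))

    def test_low_depth_na(self):
        assert math.isnan(robust_index([0.5, 0.5], [0.1, 0.1], depth_ok=False))


class TestRankDmrs:
    def _df(self, indices):
        return pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(len(indices)) * 1000,
            "end": np.arange(len(indices)) * 1000 + 100,
            "fdr": 0.01,
            "robust_index": indices,
        })

    def test_ascending_with_na_last(self):
        out = rank_dmrs(self._df([0.4, 0.1, np.nan]))
        vals = out["robust_index"].tolist()
        assert vals[0] == 0.1 and vals[1] == 0.4 and math.isnan(vals[2])

    def test_ties_fall_back_to_genomic_order(self):
        out = rank_dmrs(self._df([0.2, 0.2, 0.2]))
        assert out["start"].tolist() == [0, 1000, 2000]

    def test_top_k_selection(self):
        out = rank_dmrs(self._df(list(np.linspace(0.9, 0.1, 9))))
        top3 = out.head(3)["robust_index"].to_numpy()
        assert (top3 <= 0.3 + 1e-12).all()


class TestPipelineOnSyntheticTruth:
    def test_recovers_planted_regions(self, small_study, small_pipeline):
        called = small_pipeline.dmrs
        planted = small_study.planted
        assert len(called) >= 1
        hit = 0
        for p in planted.itertuples():
            sub = called[(called["chrom"] == p.chrom)
                         & (called["direction"] == p.direction)]
            if ((sub["start"] < p.end) & (sub["end"] > p.start)).any():
                hit += 1
        assert hit / len(planted) >= 0.8

    def test_dmr_boundaries_are_dmc_positions(self, small_pipeline):
        dmcs = small_pipeline.dmcs
        pos0 = set(zip(dmcs["chrom"], dmcs["pos"] - 1))
        for row in small_pipeline.dmrs.itertuples():
            assert (row.chrom, row.start) in pos0
            assert (row.chrom, row.end - 1) in pos0

    def test_no_two_dmrs_overlap(self, small_pipeline):
        df = small_pipeline.dmrs.sort_values(["chrom", "start"])
        for chrom, sub in df.groupby("chrom"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()

    def test_invariants_on_report(self, small_pipeline):
        df = small_pipeline.dmrs
        assert (df["n_dmc"] >= 4).all()
        assert (df["mean_diff"].abs() > 0.15).all()
        assert ((df["mean_diff"] < 0) == (df["direction"] == "hypo")).all()

    def test_writers_produce_files(self, small_pipeline, tmp_path):
        write_dmrs_bed(small_pipeline.dmrs, tmp_path / "d.bed")
        write_dmrs_tsv(small_pipeline.dmrs, tmp_path / "d.tsv")
        bed_lines = (tmp_path / "d.bed").read_text().strip().split("\n")
        assert len(bed_lines) == len(small_pipeline.dmrs)
        assert all(len(l.split("\t")) >= 10 for l in bed_lines)


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            DmrParams(step=300).validate()
        with pytest.raises(ValueError):
            DmrParams(fdr=0).validate()
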