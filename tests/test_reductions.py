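"""The score-preserving reductions and solution stitching."""

import numpy as np
import pytest

import hapmec as hm
from hapmec.matrix import ASSUMED_HET
from hapmec.oracle import ALL_HET, GENERAL, brute_force_mec
from hapmec.reductions import (
    Block,
    ReductionTrace,
    StitchError,
    _cut_positions,
)

from conftest import random_corpus


class TestMonotoneColumns:
    def test_single_allele_column_removed_with_call(self):
        m = hm.ReadMatrix.from_rows(["10-", "1-0", "-11"])
        reduced, trace = hm.remove_monotone_columns(m)
        assert trace.homozygous_calls == {0: "1"}
        assert reduced.col_ids == [1, 2]
        assert reduced.rows == ["0-", "-0", "11"]

    def test_worked_example_untouched(self, matrix_a):
        reduced, trace = hm.remove_monotone_columns(matrix_a)
        assert reduced.rows == list(matrix_a.rows)
        assert trace.homozygous_calls == {}

    def test_everything_removed(self):
        m = hm.ReadMatrix.from_rows(["0-", "0-"])
        reduced, trace = hm.remove_monotone_columns(m)
        assert reduced is None
        assert trace.homozygous_calls == {0: "0", 1: "0"}  # col 2 all-gap -> "0"
        assert sorted(trace.removed_rows) == [(0, "empty"), (1, "empty")]


class TestSingletonRemoval:
    def test_only_het_column_singletons_removed(self):
        m = hm.ReadMatrix.from_rows(["1---", "-0--", "10--"])
        reduced, trace = hm.remove_singleton_rows(m, het_columns={1})
        assert reduced.rows == ["1---", "10--"]
        assert trace.removed_rows == [(1, "singleton")]

    def test_all_het_mode_removes_all_singletons(self):
        m = hm.ReadMatrix.from_rows(["1-", "-0", "10"])
        reduced, trace = hm.remove_singleton_rows(m, het_columns={0, 1})
        assert reduced.rows == ["10"]
        assert len(trace.removed_rows) == 2

    def test_worked_example_untouched(self, matrix_a):
        reduced, _ = hm.remove_singleton_rows(matrix_a, set(range(6)))
        assert reduced.rows == list(matrix_a.rows)

    def test_reinsertion_adds_nothing_to_any_complementary_pair(self):
        rng = np.random.default_rng(3)
        base = hm.random_matrix(rng, 4, 5, gap_prob=0.2)
        singleton = "--1--"
        m = hm.ReadMatrix.from_rows(base.rows + [singleton])
        for _ in range(10):
            h = "".join(rng.choice(["0", "1"], size=5))
            pair = hm.HaplotypePair.complementary(h)
            assert hm.mec_score(m, pair) == hm.mec_score(base, pair)


class TestBlockSplit:
    def test_disjoint_reads_split(self):
        m = hm.ReadMatrix.from_rows(["10--", "--01"])
        blocks, trace = hm.split_blocks(m)
        assert [b.matrix.rows for b in blocks] == [["10"], ["01"]]
        assert trace.block_cuts == [1]

    def test_worked_example_is_one_block(self, matrix_a):
        blocks, trace = hm.split_blocks(matrix_a)
        assert len(blocks) == 1
        assert trace.block_cuts == []

    def test_single_read_one_block(self):
        blocks, _ = hm.split_blocks(hm.ReadMatrix.from_rows(["11"]))
        assert len(blocks) == 1

    def test_no_read_straddles_and_columns_partition(self):
        for m in random_corpus(seed=31, n=30):
            blocks, _ = hm.split_blocks(m)
            covered = [gid for b in blocks for gid in b.matrix.col_ids]
            assert covered == list(range(m.num_columns))
            assert sum(b.matrix.num_rows for b in blocks) == m.num_rows


class TestReducedBlockSplit:
    def test_shared_column_duplicated(self):
        m = hm.ReadMatrix.from_rows(["11-", "-11"])
        m.het_status = [ASSUMED_HET] * 3
        block = Block(matrix=m, index=0)
        rbs, trace = hm.split_reduced_blocks(block, {0, 1, 2})
        assert len(rbs) == 2
        assert rbs[0].matrix.rows == ["11"]
        assert rbs[0].col_ids == [0, 1]
        assert rbs[1].matrix.rows == ["11"]
        assert rbs[1].col_ids == [1, 2]
        assert rbs[0].last_shared and rbs[1].first_shared
        assert trace.reduced_block_boundaries == {0: [1]}

    def test_worked_example_not_cut(self, matrix_a):
        block = Block(matrix=matrix_a, index=0)
        rbs, _ = hm.split_reduced_blocks(block, set(range(6)))
        assert len(rbs) == 1
        assert rbs[0].matrix.rows == list(matrix_a.rows)

    def test_point_read_goes_left(self):
        m = hm.ReadMatrix.from_rows(["11-", "-1-", "-11"])
        block = Block(matrix=m, index=0)
        rbs, _ = hm.split_reduced_blocks(block, {0, 1, 2})
        assert rbs[0].matrix.rows == ["11", "-1"]
        assert rbs[1].matrix.rows == ["11"]


class TestMerging:
    def test_identical_rows_collapse(self):
        m = hm.ReadMatrix.from_rows(["01-", "01-", "1-0"])
        merged, trace = hm.merge_rows(m)
        assert merged.rows == ["01-", "1-0"]
        assert merged.row_weights == [2, 1]
        assert trace.row_merge_groups == [[0, 1], [2]]

    def test_triple_merge(self):
        merged, _ = hm.merge_rows(hm.ReadMatrix.from_rows(["0-", "0-", "0-"]))
        assert merged.rows == ["0-"]
        assert merged.row_weights == [3]

    def test_complementary_columns_collapse_with_flip(self):
        # columns (0,1) and (1,0): complementary, same (empty) gap pattern
        m = hm.ReadMatrix.from_rows(["01", "10"])
        merged, _ = hm.merge_columns(m)
        assert merged.num_columns == 1
        assert merged.col_weights == [2]
        assert merged.col_origin[0] == ((0, False), (1, True))

    def test_identical_gap_columns_collapse(self):
        m = hm.ReadMatrix.from_rows(["00", "11"])
        merged, _ = hm.merge_columns(m)
        assert merged.num_columns == 1
        assert merged.col_weights == [2]
        assert merged.col_origin[0] == ((0, False), (1, False))

    def test_worked_example_columns_all_distinct(self, matrix_a):
        merged, _ = hm.merge_columns(matrix_a)
        assert merged.num_columns == 6
        merged_r, _ = hm.merge_rows(matrix_a)
        assert merged_r.num_rows == 6

    def test_weighted_mec_matches_unmerged_for_orientation_respecting_pairs(self):
        # scores agree for every pair whose bits at merged members follow
        # the recorded same/flipped orientation of the group
        rng = np.random.default_rng(17)
        for m in random_corpus(seed=41, n=25, max_rows=6, max_cols=8):
            merged, _ = hm.merge_rows(m)
            merged, _ = hm.merge_columns(merged)
            for _ in range(5):
                mh = "".join(rng.choice(["0", "1"], size=merged.num_columns))
                full = ["?"] * m.num_columns
                for j in range(merged.num_columns):
                    for gid, flipped in merged.col_origin[j]:
                        full[gid] = hm.complement(mh[j]) if flipped else mh[j]
                assert "?" not in full
                pair = hm.HaplotypePair.complementary("".join(full))
                assert hm.mec_score(merged, hm.HaplotypePair.complementary(mh)) \
                    == hm.mec_score(m, pair)


class TestStitch:
    def _rb(self, rows, col_ids, block_index=0, k=0, first=False, last=False):
        m = hm.ReadMatrix.from_rows(rows)
        m.col_ids = list(col_ids)
        m.col_origin = {j: ((g, False),) for j, g in enumerate(col_ids)}
        m.het_status = [ASSUMED_HET] * len(col_ids)
        rb = hm.ReducedBlock(
            matrix=m, block_index=block_index, index_in_block=k,
            first_shared=first, last_shared=last,
        )
        rb.refresh_from_matrix()
        return rb

    def _trace(self, ncols, calls=None):
        return ReductionTrace(
            homozygous_calls=calls or {},
            original_num_rows=0,
            original_num_columns=ncols,
        )

    def test_consistent_boundary_needs_no_swap(self):
        left = self._rb(["01"], [0, 1], k=0, last=True)
        right = self._rb(["10"], [1, 2], k=1, first=True)
        sols = [
            (left, hm.HaplotypePair("01", "10"), 0),
            (right, hm.HaplotypePair("10", "01"), 0),
        ]
        result = hm.stitch(sols, self._trace(3))
        assert (result.h, result.h_prime) == ("010", "101")

    def test_mismatched_boundary_swaps_right_pair(self):
        left = self._rb(["01"], [0, 1], k=0, last=True)
        right = self._rb(["10"], [1, 2], k=1, first=True)
        sols = [
            (left, hm.HaplotypePair("01", "10"), 0),
            (right, hm.HaplotypePair("01", "10"), 0),
        ]
        result = hm.stitch(sols, self._trace(3))
        assert result.h == "010"

    def test_homozygous_call_reinserted(self):
        only = self._rb(["01"], [0, 1])
        sols = [(only, hm.HaplotypePair("01", "10"), 1)]
        result = hm.stitch(sols, self._trace(3, calls={2: "1"}))
        assert result.h == "011"
        assert result.h_prime == "101"
        assert result.zygosity == ["het", "het", "hom"]
        assert result.total_mec == 1

    def test_uncovered_column_is_an_error(self):
        only = self._rb(["01"], [0, 1])
        with pytest.raises(StitchError):
            hm.stitch([(only, hm.HaplotypePair("01", "10"), 0)], self._trace(3))


class TestEndToEndPreservation:
    """Pipeline optimum == oracle optimum on the same objective.

    In all-heterozygous mode the pipeline calls monotone columns homozygous
    before anything else, so its objective constrains complementarity only
    on the surviving columns; the oracle reference is therefore taken on
    the monotone-reduced matrix (score preserved: removed columns and
    emptied rows cost 0).  General mode imposes no such assumption and is
    compared on the untouched matrix.
    """

    def test_pipeline_mec_equals_oracle_allhet(self):
        for m in random_corpus(seed=101, n=60):
            reduced, _ = hm.remove_monotone_columns(m)
            expected = 0 if reduced is None else brute_force_mec(reduced, ALL_HET)[0]
            result, _ = hm.assemble(m, mode="allhet", model="new", time_limit=60)
            assert result.total_mec == expected
            pair = hm.HaplotypePair(result.h, result.h_prime)
            assert hm.mec_score(m, pair) == expected

    def test_pipeline_mec_equals_oracle_general(self):
        for m in random_corpus(seed=103, n=60):
            expected, _ = brute_force_mec(m, GENERAL)
            result, _ = hm.assemble(m, mode="general", model="new", time_limit=60)
            assert result.total_mec == expected
            pair = hm.HaplotypePair(result.h, result.h_prime)
            assert hm.mec_score(m, pair) == expected
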