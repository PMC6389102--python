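"""The four ILP formulations: sizes, truth tables, and optima."""

import itertools

import pytest

import hapmec as hm
from hapmec import ilp
from hapmec.matrix import GAP
from hapmec.oracle import ALL_HET, GENERAL, brute_force_mec

from conftest import random_corpus


def _count_sums(matrix):
    """(sum |J_i0|+|J_i1| over rows, per intrinsic set) helpers."""
    return sum(len(r) - r.count(GAP) for r in matrix.rows)


class TestModelSizes:
    def test_worked_example_all_het(self, matrix_a):
        new = ilp.build_new_model_a(matrix_a)
        old = ilp.build_old_model_a(matrix_a)
        assert ilp.model_stats(new) == (32, 20)  # 6x + 6z + 20t; one per entry
        assert ilp.model_stats(old) == (32, 60)

    def test_worked_example_general(self, matrix_a):
        new = ilp.build_new_model_g(matrix_a, frozenset())
        old = ilp.build_old_model_g(matrix_a, frozenset())
        assert ilp.model_stats(new) == (58, 40)
        assert ilp.model_stats(old) == (58, 120)

    def test_general_with_all_columns_intrinsic_matches_all_het(self, matrix_a):
        intr = frozenset(range(6))
        new = ilp.build_new_model_g(matrix_a, intr)
        old = ilp.build_old_model_g(matrix_a, intr)
        assert new.num_constraints == 20
        assert old.num_constraints == 60

    def test_single_entry_models(self):
        m = hm.ReadMatrix.from_rows(["1"])
        assert ilp.build_new_model_a(m).num_constraints == 1
        assert ilp.build_old_model_a(m).num_constraints == 3

    def test_count_formulas_on_random_corpus(self):
        for m in random_corpus(seed=57, n=30):
            nnz = _count_sums(m)
            assert ilp.build_new_model_a(m).num_constraints == nnz
            assert ilp.build_old_model_a(m).num_constraints == 3 * nnz
            # I = empty: every entry lies in a J-bar set
            assert ilp.build_new_model_g(m, frozenset()).num_constraints == 2 * nnz
            assert ilp.build_old_model_g(m, frozenset()).num_constraints == 6 * nnz
            # mixed intrinsic set
            intr = frozenset(range(0, m.num_columns, 2))
            n_in = sum(
                1
                for row in m.rows
                for j, ch in enumerate(row)
                if ch != GAP and j in intr
            )
            n_out = nnz - n_in
            assert ilp.build_new_model_g(m, intr).num_constraints == n_in + 2 * n_out
            assert ilp.build_old_model_g(m, intr).num_constraints == 3 * n_in + 6 * n_out


class TestTruthTables:
    """Constraint-minimal t/u reproduce the mismatch indicators."""

    def test_entry_zero_penalty_is_equality_indicator(self):
        for x, z in itertools.product((0, 1), repeat=2):
            t = max(0, x + z - 1)
            assert (1 - x - z + 2 * t) == (1 if x == z else 0)

    def test_entry_one_penalty_is_inequality_indicator(self):
        for x, z in itertools.product((0, 1), repeat=2):
            t = max(0, z - x)
            assert (x - z + 2 * t) == (1 if x != z else 0)

    def test_general_entry_zero_t_plus_u(self):
        # mismatch on the aligned haplotype: allele 0 vs h bit x / h' bit y
        for x, y, z in itertools.product((0, 1), repeat=3):
            t = max(0, x + z - 1)
            u = max(0, y - z)
            expected = x if z == 1 else y
            assert t + u == expected

    def test_general_entry_one_t_plus_u(self):
        for x, y, z in itertools.product((0, 1), repeat=3):
            t = max(0, z - x)
            u = max(0, 1 - y - z)
            expected = (1 - x) if z == 1 else (1 - y)
            assert t + u == expected


class TestOptima:
    def test_new_model_a_solves_worked_example(self, matrix_a):
        model = ilp.build_new_model_a(matrix_a)
        res = ilp.solve(model, 60)
        assert res.status == ilp.STATUS_OPTIMAL
        assert res.objective == 2
        pair, assignment, mec = ilp.decode(model, res)
        assert mec == 2
        assert pair.h_prime == hm.complement(pair.h)

    def test_new_model_g_solves_worked_example(self, matrix_a):
        model = ilp.build_new_model_g(matrix_a, frozenset())
        res = ilp.solve(model, 60)
        assert res.status == ilp.STATUS_OPTIMAL
        assert res.objective == 2

    def test_conflict_free_matrix_scores_zero(self):
        m = hm.ReadMatrix.from_rows(["11", "11"])
        res = ilp.solve(ilp.build_new_model_a(m), 60)
        assert res.objective == 0

    def test_unknown_solver_rejected(self, matrix_a):
        model = ilp.build_new_model_a(matrix_a)
        with pytest.raises(ilp.SolverError):
            ilp.solve(model, 60, solver="cplex")

    def test_weighted_matrix_objective_counts_multiplicities(self):
        # one conflicting read duplicated via weight: errors scale with w
        m = hm.ReadMatrix.from_rows(["11", "00", "10"], row_weights=[1, 1, 3])
        res = ilp.solve(ilp.build_new_model_a(m), 60)
        expected, _ = brute_force_mec(m, ALL_HET)
        assert res.objective == expected

    def test_all_four_models_match_oracle_on_random_corpus(self):
        for m in random_corpus(seed=211, n=40):
            oracle_a, _ = brute_force_mec(m, ALL_HET)
            oracle_g, _ = brute_force_mec(m, GENERAL)
            obj = {}
            for name, model in (
                ("new_a", ilp.build_new_model_a(m)),
                ("old_a", ilp.build_old_model_a(m)),
                ("new_g", ilp.build_new_model_g(m, frozenset())),
                ("old_g", ilp.build_old_model_g(m, frozenset())),
            ):
                res = ilp.solve(model, 60)
                assert res.status == ilp.STATUS_OPTIMAL
                obj[name] = res.objective
            assert obj["new_a"] == obj["old_a"] == oracle_a
            assert obj["new_g"] == obj["old_g"] == oracle_g
            assert oracle_g <= oracle_a

    def test_decode_alignment_matches_distances(self, matrix_a):
        model = ilp.build_new_model_a(matrix_a)
        res = ilp.solve(model, 60)
        pair, assignment, mec = ilp.decode(model, res)
        # every aligned-to-h row is at least as close to h as to h'
        for row, to_h in zip(matrix_a.rows, assignment.to_h):
            d_h = hm.mismatch_distance(pair.h, row)
            d_hp = hm.mismatch_distance(pair.h_prime, row)
            assert (d_h <= d_hp) if to_h else (d_hp <= d_h)


class TestLpExport:
    def test_lp_file_is_readable_text(self, matrix_a, tmp_path):
        model = ilp.build_new_model_a(matrix_a)
        path = tmp_path / "model.lp"
        ilp.write_lp(model, path)
        text = path.read_text()
        assert text.startswith("\\ NewModelA")
        assert "Minimize" in text and "Binary" in text and text.rstrip().endswith("End")
        assert text.count("c20:") == 1 and "c21:" not in text
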