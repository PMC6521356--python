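"""Saltelli estimators against closed forms and the brute-force oracle."""

import numpy as np
import pytest

import her4jakstat as h
from her4jakstat import bench

N_BIG = 2 ** 13


def unit_space(k):
    return h.ParameterSpace([(f"x{i+1}", 0.0, 1.0, "linear") for i in range(k)])


@pytest.fixture(scope="module")
def ishigami_result():
    fn = bench.ishigami_function()
    design = h.saltelli_design(unit_space(3), N_BIG)
    bundle = h.evaluate_design(design, fn.evaluator)
    return h.analyze(bundle, design, "ishigami"), fn


class TestFirstOrder:
    def test_single_active_input(self):
        design = h.saltelli_design(unit_space(2), N_BIG)
        bundle = h.evaluate_design(design, lambda x: x[0])
        res = h.analyze(bundle, design)
        assert res.S1[0] == pytest.approx(1.0, abs=0.02)
        assert res.S1[1] == pytest.approx(0.0, abs=0.02)
        assert res.ST[1] == pytest.approx(0.0, abs=0.02)

    def test_ishigami_matches_closed_form(self, ishigami_result):
        res, fn = ishigami_result
        assert res.S1 == pytest.approx(fn.closed_form_S1, abs=0.02)

    def test_constant_output_rejected(self):
        design = h.saltelli_design(unit_space(2), 64)
        bundle = h.evaluate_design(design, lambda x: 3.0)
        with pytest.raises(ValueError, match="variance"):
            h.analyze(bundle, design)


class TestTotalEffect:
    def test_additive_model_has_equal_s1_and_st(self):
        fn = bench.additive_linear(2)
        design = h.saltelli_design(unit_space(2), N_BIG)
        bundle = h.evaluate_design(design, fn.evaluator)
        res = h.analyze(bundle, design)
        assert res.ST == pytest.approx(res.S1, abs=0.02)

    def test_ishigami_total_effects(self, ishigami_result):
        res, fn = ishigami_result
        assert res.ST == pytest.approx(fn.closed_form_ST, abs=0.02)
        # x3 is a pure-interaction input: invisible to S1, not to ST
        assert res.ST[2] - res.S1[2] > 0.2

    def test_st_dominates_s1(self, ishigami_result):
        res, _ = ishigami_result
        assert np.all(res.ST >= res.S1 - 0.02)


class TestDecomposition:
    def test_additive_first_order_indices_sum_to_one(self):
        fn = bench.additive_linear(3)
        design = h.saltelli_design(unit_space(3), N_BIG)
        bundle = h.evaluate_design(design, fn.evaluator)
        res = h.analyze(bundle, design)
        assert res.S1.sum() == pytest.approx(1.0, abs=0.02)

    def test_lengths_match_dimension(self, ishigami_result):
        res, _ = ishigami_result
        assert len(res.S1) == len(res.ST) == 3

    def test_affine_output_invariance(self):
        fn = bench.ishigami_function()
        design = h.saltelli_design(unit_space(3), 2 ** 11)
        b1 = h.evaluate_design(design, fn.evaluator)
        b2 = h.evaluate_design(design, lambda x: -2.5 * fn.evaluator(x) + 7.0)
        r1, r2 = h.analyze(b1, design), h.analyze(b2, design)
        # exact in expectation; finite-N cross terms leave O(1/N) residue
        assert r2.S1 == pytest.approx(r1.S1, abs=5e-3)
        assert r2.ST == pytest.approx(r1.ST, abs=5e-3)


class TestOracleEquivalence:
    def test_saltelli_matches_double_loop(self, ishigami_result):
        res, fn = ishigami_result
        for i in range(3):
            dl = bench.double_loop_sobol(fn.evaluator, 3, i, seed=i,
                                         n_outer=1024, n_inner=256)
            assert res.S1[i] == pytest.approx(dl, abs=0.03)

    def test_total_effect_matches_double_loop(self, ishigami_result):
        res, fn = ishigami_result
        dl = bench.double_loop_sobol(fn.evaluator, 3, 2, seed=9, total=True,
                                     n_outer=1024, n_inner=256)
        assert res.ST[2] == pytest.approx(dl, abs=0.03)


class TestEvaluateDesign:
    def test_vectors_match_direct_evaluation(self):
        design = h.saltelli_design(unit_space(3), 16)
        f = lambda x: x[0] + 2 * x[1] * x[2]
        bundle = h.evaluate_design(design, f)
        assert bundle.fA == pytest.approx([f(r) for r in design.A])
        assert bundle.fB == pytest.approx([f(r) for r in design.B])
        assert len(bundle.fAB) == 3 and len(bundle.fBA) == 3

    def test_failed_rows_excluded_pairwise(self):
        design = h.saltelli_design(unit_space(2), 32)

        def flaky(x):
            if x[0] > 0.9:
                raise ValueError("synthetic failure")
            return x[0]

        bundle = h.evaluate_design(design, flaky)
        assert bundle.failures
        assert bundle.N == 32 - len(bundle.failures)
        assert all(len(v) == bundle.N for v in bundle.fAB + bundle.fBA)

    def test_pathological_bounds_rejected(self):
        design = h.saltelli_design(unit_space(2), 16)

        def broken(x):
            raise ValueError("always fails")

        with pytest.raises(RuntimeError, match="pathological"):
            h.evaluate_design(design, broken)


class TestRanking:
    def _result(self, st_values, ids=None):
        k = len(st_values)
        ids = ids or [f"p{i+1}" for i in range(k)]
        return h.SensitivityResult("out", ids, np.zeros(k),
                                   np.asarray(st_values, float), 0.0, 1.0, 8)

    def test_sorted_by_total_effect(self):
        top = h.rank_top(self._result([0.5, 0.1, 0.3]))
        assert [t[0] for t in top] == ["p1", "p3", "p2"]

    def test_n_exceeding_k_returns_all(self):
        assert len(h.rank_top(self._result([0.2, 0.1]), n=10)) == 2

    def test_ties_broken_lexicographically(self):
        top = h.rank_top(self._result([0.3, 0.3, 0.3], ids=["c", "a", "b"]))
        assert [t[0] for t in top] == ["a", "b", "c"]

    def test_negative_estimates_clipped_for_sorting_only(self):
        top = h.rank_top(self._result([-0.05, 0.2]))
        assert top[0][0] == "p2"
        assert top[1][2] == pytest.approx(-0.05)  # raw value preserved
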