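"""Fitness, penalties, repair contract and the enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugswarm.objective import (
    CriterionWeights,
    Evaluator,
    SelectionVector,
    brute_force_optimum,
    fitness,
    is_feasible,
    penalize,
    repair,
)


class TestFitness:
    def test_best_case_bound_alpha_plus_gamma(self, small_planted):
        """Records with perfect rating/reviews and zero severity hit alpha+gamma."""
        table = small_planted["table"]
        df = table.df
        # synthesize a 2-record perfect table by overwriting the normalized cols
        t = table
        sub = t.df.iloc[:2].copy()
        sub["rating_norm"], sub["severity_norm"], sub["reviews_norm"] = 1.0, 0.0, 1.0
        perfect = type(t)(df=sub)
        fit = fitness(SelectionVector([0, 1], 2), perfect, CriterionWeights())
        assert fit.raw_fitness == pytest.approx(0.7)

    def test_worst_case_bound_minus_beta(self, small_planted):
        t = small_planted["table"]
        sub = t.df.iloc[:2].copy()
        sub["rating_norm"], sub["severity_norm"], sub["reviews_norm"] = 0.0, 1.0, 0.0
        worst = type(t)(df=sub)
        fit = fitness(SelectionVector([0, 1], 2), worst, CriterionWeights())
        assert fit.raw_fitness == pytest.approx(-0.3)

    def test_matches_loop_based_oracle_on_random_selections(self, small_planted, rng):
        table = small_planted["table"]
        wts = CriterionWeights()
        rating, severity, reviews = table.criteria_arrays()
        for _ in range(100):
            idx = rng.choice(table.n_drugs, size=4, replace=False)
            fit = fitness(SelectionVector(idx, 4), table, wts)
            expected = (
                wts.alpha * sum(rating[i] for i in idx) / 4
                - wts.beta * sum(severity[i] for i in idx) / 4
                + wts.gamma * sum(reviews[i] for i in idx) / 4
            )
            assert fit.raw_fitness == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariant(self, small_planted, rng):
        table = small_planted["table"]
        idx = rng.choice(table.n_drugs, size=4, replace=False)
        f1 = fitness(SelectionVector(idx, 4), table, CriterionWeights())
        f2 = fitness(SelectionVector(idx[::-1], 4), table, CriterionWeights())
        assert f1.raw_fitness == pytest.approx(f2.raw_fitness)

    def test_out_of_range_indices_never_crash(self, small_planted):
        table = small_planted["table"]
        fit = fitness(SelectionVector([0, 999], 2), table, CriterionWeights())
        assert np.isfinite(fit.raw_fitness)


class TestPenalize:
    def _fit(self, table, sel):
        return fitness(sel, table, CriterionWeights())

    def test_feasible_selection_is_unpenalized(self, small_planted):
        table = small_planted["table"]
        sel = SelectionVector([0, 1, 2], 3)
        fit = penalize(sel, self._fit(table, sel), 1.0, 1.0, table.n_drugs)
        assert fit.p_equality == 0 and fit.p_uniqueness == 0
        assert fit.penalized_fitness == fit.raw_fitness

    def test_duplicate_costs_lambda2(self, small_planted):
        table = small_planted["table"]
        sel = SelectionVector([0, 0, 2], 3)
        fit = penalize(sel, self._fit(table, sel), 1.0, 1.0, table.n_drugs)
        assert fit.p_uniqueness == 1
        assert fit.penalized_fitness == pytest.approx(fit.raw_fitness - 1.0)

    def test_wrong_length_costs_lambda1(self, small_planted):
        table = small_planted["table"]
        sel = SelectionVector([0, 1, 2, 3], 3)
        fit = penalize(sel, self._fit(table, sel), 1.0, 1.0, table.n_drugs)
        assert fit.p_equality == 1
        assert fit.penalized_fitness == pytest.approx(fit.raw_fitness - 1.0)

    def test_negative_lambda_rejected(self, small_planted):
        table = small_planted["table"]
        sel = SelectionVector([0, 1, 2], 3)
        with pytest.raises(ValueError):
            penalize(sel, self._fit(table, sel), -1.0, 1.0, table.n_drugs)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        idx=st.lists(st.integers(-3, 15), min_size=1, max_size=6),
        lam=st.floats(0.0, 5.0),
    )
    def test_penalty_is_monotone_in_violations(self, small_planted, idx, lam):
        """Adding a violation never increases the penalized score."""
        table = small_planted["table"]
        sel = SelectionVector(np.array(idx), 3)
        fit = penalize(sel, self._fit(table, sel), lam, lam, table.n_drugs)
        worse = SelectionVector(np.append(sel.indices, sel.indices[0]), 3)
        wfit = penalize(worse, self._fit(table, worse), lam, lam, table.n_drugs)
        n_viol = fit.p_equality + fit.p_uniqueness
        n_viol_worse = wfit.p_equality + wfit.p_uniqueness
        assert n_viol_worse >= n_viol


class TestRepair:
    def test_rounding_only_when_already_unique(self, rng):
        out = repair(np.array([2.4, 2.6, 7.0]), 10, rng)
        assert out.tolist() == [2, 3, 7]

    def test_forced_uniqueness_at_d_equal_k(self, rng):
        out = repair(np.array([1.0, 1.0, 1.0]), 3, rng)
        assert out[0] == 1
        assert sorted(out.tolist()) == [0, 1, 2]

    def test_identity_on_feasible_integer_positions(self, rng):
        out = repair(np.array([4.0, 0.0, 9.0]), 10, rng)
        assert out.tolist() == [4, 0, 9]

    def test_d_smaller_than_k_is_an_error(self, rng):
        with pytest.raises(ValueError):
            repair(np.zeros(5), 3, rng)

    def test_always_feasible_on_random_inputs(self, rng):
        """Decode contract: 10,000 arbitrary real vectors all map to feasible sets."""
        for _ in range(10_000):
            raw = rng.normal(25, 40, size=5)
            out = repair(raw, 50, rng)
            assert is_feasible(out, 5, 50)


class TestBruteForce:
    def test_enumerates_all_subsets(self, small_planted):
        table = small_planted["table"]
        ev = Evaluator(table)
        sel, val = brute_force_optimum(table, 3)
        # C(12,3) = 220 subsets: verify the reported optimum beats 219 others
        from itertools import combinations

        scores = [
            ev.score_one(np.array(c), k=3) for c in combinations(range(12), 3)
        ]
        assert len(scores) == 220
        assert val == pytest.approx(max(scores))

    def test_single_dominant_record_wins_k1(self, small_planted):
        table = small_planted["table"]
        t = table
        sub = t.df.iloc[:4].copy()
        sub["rating_norm"] = [1.0, 0.1, 0.2, 0.3]
        sub["severity_norm"] = [0.0, 0.9, 0.8, 0.7]
        sub["reviews_norm"] = [1.0, 0.2, 0.1, 0.0]
        dominated = type(t)(df=sub)
        sel, _ = brute_force_optimum(dominated, 1)
        assert sel.indices.tolist() == [0]

    def test_recovers_planted_subset(self, small_planted):
        assert (
            small_planted["optimum"].indices.tolist()
            == small_planted["planted"].tolist()
        )

    def test_budget_refusal(self, small_planted):
        with pytest.raises(ValueError, match="budget"):
            brute_force_optimum(small_planted["table"], 3, budget=10)


class TestEvaluator:
    def test_counts_every_evaluation(self, small_planted, rng):
        ev = Evaluator(small_planted["table"])
        ev.score_many(np.array([[0, 1, 2], [3, 4, 5]]))
        ev.score_one(np.array([1, 2, 3]))
        assert ev.n_evals == 3

    def test_matrix_scores_match_scalar_path(self, small_planted, rng):
        table = small_planted["table"]
        ev = Evaluator(table)
        idx = np.stack([rng.choice(12, 3, replace=False) for _ in range(20)])
        batch = ev.score_many(idx)
        for row, score in zip(idx, batch):
            sel = SelectionVector(row, 3)
            fit = penalize(
                sel, fitness(sel, table, ev.weights), 1.0, 1.0, table.n_drugs
            )
            assert score == pytest.approx(fit.penalized_fitness, abs=1e-12)

    def test_feasibility_assertion_trips_on_duplicates(self, small_planted):
        ev = Evaluator(small_planted["table"], check_feasible=True)
        with pytest.raises(AssertionError):
            ev.score_many(np.array([[1, 1, 2]]))
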