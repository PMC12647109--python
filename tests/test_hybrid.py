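"""Hybrid PSO-EAVOA: schedules, Levy steps, opposition init, full-run behaviour."""

import numpy as np
import pytest

from drugswarm.baselines import _random_init
from drugswarm.hybrid import (
    HybridSchedule,
    accel_coefficients,
    hybrid_run,
    hybrid_step,
    hybrid_velocity_update,
    levy_sigma,
    levy_step,
    opposition_init,
)
from drugswarm.objective import Evaluator, is_feasible


class TestSchedules:
    @pytest.mark.parametrize(
        "t,T,c1,c2", [(0, 100, 2.5, 0.5), (100, 100, 0.5, 2.5), (25, 100, 2.0, 1.0)]
    )
    def test_acceleration_coefficients(self, t, T, c1, c2):
        assert accel_coefficients(t, T) == pytest.approx((c1, c2))

    def test_coefficients_sum_is_constant(self):
        for t in range(0, 101, 7):
            c1, c2 = accel_coefficients(t, 100)
            assert c1 + c2 == pytest.approx(3.0)

    def test_invalid_phase_fractions_rejected(self):
        with pytest.raises(ValueError):
            HybridSchedule(mid_phase_frac=0.8, late_phase_frac=0.7)


class TestLevy:
    def test_mantegna_sigma_closed_form(self):
        assert levy_sigma(1.5) == pytest.approx(0.6965745025576967, abs=1e-9)

    def test_beta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            levy_sigma(2.5)

    def test_steps_are_symmetric_and_heavy_tailed(self):
        rng = np.random.default_rng(99)
        steps = levy_step(100_000, 1.5, rng)
        # symmetric: mean within 3 sigma of 0 using a trimmed scale estimate
        trimmed = steps[np.abs(steps) < np.quantile(np.abs(steps), 0.99)]
        assert abs(np.mean(trimmed)) < 3 * np.std(trimmed) / np.sqrt(len(trimmed))
        # heavy tails: excess kurtosis far above the Gaussian's 0
        from scipy import stats

        assert stats.kurtosis(steps) > 10


class TestOppositionInit:
    def test_opposite_of_endpoint(self):
        # x=0 maps to D-1 and back: the mirror is an involution
        D = 10
        x = np.zeros(3)
        opp = (D - 1) - x
        assert opp.tolist() == [9.0, 9.0, 9.0]
        assert np.array_equal((D - 1) - opp, x)

    def test_keeps_best_half_of_mirrored_pool(self, small_planted):
        ev = Evaluator(small_planted["table"])
        rng = np.random.default_rng(4)
        state = opposition_init(ev, k=3, n_particles=8, rng=rng, T=10)
        assert state.positions.shape == (8, 3)
        assert ev.n_evals == 16
        assert state.gbest_score == state.pbest_scores.max()

    def test_beats_plain_random_init_on_average(self, small_planted):
        """Paired over 100 seeds: mean initial best with opposition >= without."""
        ev_proto = small_planted["table"]
        diffs = []
        for seed in range(100):
            ev1 = Evaluator(ev_proto)
            ev2 = Evaluator(ev_proto)
            s_obl = opposition_init(
                ev1, 3, 10, np.random.default_rng(seed), T=1
            ).gbest_score
            s_plain = _random_init(
                ev2, 3, 10, np.random.default_rng(seed), T=1
            ).gbest_score
            diffs.append(s_obl - s_plain)
        assert np.mean(diffs) >= 0


class TestVelocityUpdate:
    def test_fixed_point_when_all_attractors_coincide(self, rng):
        x = np.array([1.0, 2.0, 3.0])
        new_x, new_v = hybrid_velocity_update(
            x, np.zeros(3), x, x, w=0.7, c1=2.0, c2=2.0, rng=rng
        )
        assert np.allclose(new_x, x)
        assert np.allclose(new_v, 0.0)

    def test_pure_attraction_jumps_to_leader(self):
        """w=0, c2=0, c1=1 with r1 forced to 1 lands exactly on the leader."""

        class OnesRng:
            def random(self, n):
                return np.ones(n)

        x = np.array([0.0, 0.0])
        leader = np.array([5.0, 7.0])
        new_x, _ = hybrid_velocity_update(
            x, np.zeros(2), leader, np.zeros(2), w=0.0, c1=1.0, c2=0.0, rng=OnesRng()
        )
        assert np.allclose(new_x, leader)

    def test_velocity_stays_bounded_with_contracting_inertia(self, small_planted):
        """No divergence: bounded attractors and w<1 keep |v| finite over 1,000 steps."""
        rng = np.random.default_rng(0)
        for seed in range(20):
            x = rng.uniform(0, 11, 3)
            v = np.zeros(3)
            leader = rng.uniform(0, 11, 3)
            gbest = rng.uniform(0, 11, 3)
            for _ in range(1000):
                x, v = hybrid_velocity_update(
                    x, v, leader, gbest, w=0.7, c1=1.5, c2=1.5, rng=rng
                )
                x = np.clip(x, 0, 11)
            assert np.all(np.abs(v) < 1e6)


class TestHybridStep:
    def _state(self, small_planted, T=100, seed=0, n=6):
        ev = Evaluator(small_planted["table"])
        rng = np.random.default_rng(seed)
        return ev, rng, opposition_init(ev, 3, n, rng, T)

    def test_all_branches_reachable_over_a_run(self, small_planted):
        table = small_planted["table"]
        r = hybrid_run(table, k=3, seed=1, n_particles=6, n_iter=100)
        assert r.extras["branch_early"] > 0
        assert r.extras["branch_mid"] > 0
        assert r.extras["branch_late"] > 0

    def test_late_phase_threshold_arithmetic(self, small_planted):
        ev, rng, state = self._state(small_planted, T=100)
        state.iteration = 80  # next step is t=81 > 0.7*100
        counters: dict = {}
        hybrid_step(state, ev, rng, counters=counters)
        assert counters["branch_late"] == state.n_particles
        assert counters["branch_mid"] == counters["branch_early"] == 0

    def test_stagnant_particle_is_restarted(self, small_planted):
        ev, rng, state = self._state(small_planted)
        state.no_improve[:] = 6
        before = state.positions.copy()
        counters: dict = {}
        hybrid_step(state, ev, rng, counters=counters)
        assert counters["restarts"] == state.n_particles
        assert not np.allclose(state.positions[1], before[1])

    def test_gbest_survives_in_swarm_and_never_decreases(self, small_planted):
        ev, rng, state = self._state(small_planted)
        for _ in range(30):
            prev_gbest = state.gbest_position.copy()
            prev_score = state.gbest_score
            hybrid_step(state, ev, rng)
            assert state.gbest_score >= prev_score
            # the previous global best exists somewhere in the swarm
            assert np.any(
                np.all(state.pbest_positions == prev_gbest, axis=1)
                & (state.pbest_scores >= prev_score - 1e-12)
            ) or state.gbest_score > prev_score


class TestHybridRun:
    def test_same_seed_is_bit_identical(self, small_planted):
        table = small_planted["table"]
        r1 = hybrid_run(table, k=3, seed=9, n_particles=8, n_iter=60)
        r2 = hybrid_run(table, k=3, seed=9, n_particles=8, n_iter=60)
        assert np.array_equal(r1.curve, r2.curve)
        assert r1.selection.indices.tolist() == r2.selection.indices.tolist()

    def test_curve_monotone_and_selection_feasible(self, small_planted):
        table = small_planted["table"]
        for seed in range(5):
            r = hybrid_run(table, k=3, seed=seed, n_particles=8, n_iter=60)
            assert np.all(np.diff(r.curve) >= 0)
            assert is_feasible(r.selection.indices, 3, table.n_drugs)
            assert len(r.curve) == 60

    def test_all_evaluations_feasible_under_check(self, small_planted):
        table = small_planted["table"]
        ev = Evaluator(table, check_feasible=True)
        r = hybrid_run(table, k=3, seed=3, n_particles=8, n_iter=50, evaluator=ev)
        assert ev.n_infeasible_seen == 0

    def test_never_exceeds_brute_force_optimum(self, small_planted):
        table = small_planted["table"]
        opt = small_planted["optimum_value"]
        for seed in range(10):
            r = hybrid_run(table, k=3, seed=seed, n_particles=10, n_iter=80)
            assert r.score <= opt + 1e-12

    def test_iteration_evals_double_with_t(self, small_planted):
        """Countable complexity contract: per-iteration evaluations scale as Np*T."""
        table = small_planted["table"]
        r1 = hybrid_run(table, k=3, seed=5, n_particles=8, n_iter=40)
        r2 = hybrid_run(table, k=3, seed=5, n_particles=8, n_iter=80)
        assert r2.n_evals_iter == 2 * r1.n_evals_iter

    def test_total_evals_double_with_population(self, small_planted):
        table = small_planted["table"]
        r1 = hybrid_run(table, k=3, seed=5, n_particles=6, n_iter=40)
        r2 = hybrid_run(table, k=3, seed=5, n_particles=12, n_iter=40)
        assert r2.n_evals_total == 2 * r1.n_evals_total
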