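"""Hybrid PSO-EAVOA: phase-switched swarm search with Levy mutation.

The hybrid replaces PSO's personal-best attractor with a vulture leader drawn
from the swarm's elite (RVSS), and schedules three qualitatively different
update modes over the run:

* early phase (t <= 0.4 T): vulture-guided velocity updates or coarse integer
  noise — exploration;
* mid phase (0.4 T < t <= 0.7 T): contraction toward the global best with a
  decaying integer perturbation — balanced search;
* late phase (t > 0.7 T): gene swaps with the global best or Levy-flight
  perturbations — exploitation with occasional long jumps.

Opposition-based initialization, periodic Levy mutation, stagnation restarts,
worst-particle replacement by the global best and top-2 elite preservation
round out the scheme; the global best is non-decreasing by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from drugswarm.baselines import (
    OptimizerResult,
    SwarmState,
    _decode_all,
    _update_bests,
    inertia_weight,
    select_leader,
)
from drugswarm.data import DrugTable
from drugswarm.objective import CriterionWeights, Evaluator, SelectionVector

__all__ = [
    "HybridSchedule",
    "opposition_init",
    "accel_coefficients",
    "levy_sigma",
    "levy_step",
    "hybrid_velocity_update",
    "hybrid_step",
    "hybrid_run",
]


@dataclass
class HybridSchedule:
    """All tunable constants of the hybrid update schedule.

    Defaults are the printed configuration: inertia decays 0.9 -> 0.4, the
    cognitive coefficient c1 decays 2.5 -> 0.5 while the social coefficient c2
    grows 0.5 -> 2.5, phase boundaries sit at 0.4 T and 0.7 T, a Levy mutation
    sweeps the swarm every 20 iterations, particles restart after 6 stagnant
    iterations, the top 2 elites are preserved, and late-phase gene swaps copy
    2 genes from the global best.
    """

    wmax: float = 0.9
    wmin: float = 0.4
    c1_start: float = 2.5
    c1_slope: float = 2.0
    c2_start: float = 0.5
    c2_slope: float = 2.0
    late_phase_frac: float = 0.7
    mid_phase_frac: float = 0.4
    levy_period: int = 20
    restart_threshold: int = 6
    elite_count: int = 2
    gene_swap_count: int = 2
    mid_influence: float = 0.7
    mid_perturb_range: tuple[int, int] = (-3, 3)
    early_perturb_range: tuple[int, int] = (-5, 5)
    levy_beta: float = 1.5
    levy_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.mid_phase_frac < self.late_phase_frac < 1:
            raise ValueError("phase fractions must satisfy 0 < mid < late < 1")
        if self.levy_period < 1 or self.elite_count < 1:
            raise ValueError("levy_period and elite_count must be >= 1")


def accel_coefficients(t: int, T: int, sched: HybridSchedule | None = None) -> tuple[float, float]:
    """Time-varying acceleration coefficients: (2.5 - 2 t/T, 0.5 + 2 t/T)."""
    if T < 1:
        raise ValueError("max iteration T must be >= 1")
    if not 0 <= t <= T:
        raise ValueError(f"iteration t={t} outside [0, {T}]")
    s = sched or HybridSchedule()
    return s.c1_start - s.c1_slope * t / T, s.c2_start + s.c2_slope * t / T


def levy_sigma(beta: float) -> float:
    """Mantegna scale sigma_u for the numerator Gaussian of a Levy step."""
    if not 1.0 < beta <= 2.0:
        raise ValueError(f"levy beta must be in (1, 2], got {beta}")
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_step(
    dim: int, beta: float, rng: np.random.Generator, scale: float = 1.0
) -> np.ndarray:
    """Heavy-tailed Levy-flight step by the Mantegna construction.

    step_i = u_i / |v_i|^(1/beta) with u ~ N(0, sigma_u^2), v ~ N(0, 1);
    symmetric around 0 with occasional very large excursions.
    """
    sigma = levy_sigma(beta)
    u = rng.normal(0.0, sigma, size=dim)
    v = rng.normal(0.0, 1.0, size=dim)
    return scale * u / np.abs(v) ** (1.0 / beta)


def opposition_init(
    evaluator: Evaluator,
    k: int,
    n_particles: int,
    rng: np.random.Generator,
    T: int,
) -> SwarmState:
    """Opposition-based initialization: keep the best Np of Np pairs.

    Each uniform position x in [0, D-1]^k is paired with its coordinate-wise
    mirror (D-1) - x; all 2 Np decoded candidates are evaluated and the Np
    best become the initial swarm (zero velocities).
    """
    if n_particles < 2:
        raise ValueError("need at least 2 particles")
    D = evaluator.n_drugs
    base = rng.uniform(0, D - 1, size=(n_particles, k))
    opposite = (D - 1) - base
    pool = np.vstack([base, opposite])
    decoded = _decode_all(pool, D, rng)
    scores = evaluator.score_many(decoded)
    keep = np.argsort(scores)[::-1][:n_particles]
    best = int(keep[0])
    return SwarmState(
        positions=pool[keep],
        velocities=np.zeros((n_particles, k)),
        pbest_positions=decoded[keep].astype(float),
        pbest_scores=scores[keep].copy(),
        gbest_position=decoded[best].astype(float),
        gbest_score=float(scores[best]),
        no_improve=np.zeros(n_particles, dtype=int),
        iteration=0,
        max_iteration=T,
    )


def hybrid_velocity_update(
    position: np.ndarray,
    velocity: np.ndarray,
    best_vulture: np.ndarray,
    gbest: np.ndarray,
    w: float,
    c1: float,
    c2: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """PSO-style update with the vulture leader in place of the personal best.

    v <- w v + c1 r1 (best_vulture - x) + c2 r2 (gbest - x);  x <- x + v,
    with fresh r1, r2 ~ U(0,1) per dimension.
    """
    k = len(position)
    r1 = rng.random(k)
    r2 = rng.random(k)
    v = w * velocity + c1 * r1 * (best_vulture - position) + c2 * r2 * (gbest - position)
    return position + v, v


def hybrid_step(
    state: SwarmState,
    evaluator: Evaluator,
    rng: np.random.Generator,
    sched: HybridSchedule | None = None,
    counters: dict | None = None,
) -> SwarmState:
    """One hybrid iteration (1-based iteration counter inside the run loop).

    Applies exactly one phase branch per particle, then the periodic Levy
    sweep and stagnation restarts, decodes and evaluates every particle once,
    updates the bests, replaces the worst particle with the global best and
    re-inserts the pre-update top elites over the worst slots if their scores
    would otherwise be lost.
    """
    sched = sched or HybridSchedule()
    D = evaluator.n_drugs
    Np, k = state.positions.shape
    t = state.iteration + 1  # this step produces the state after iteration t
    T = state.max_iteration
    w = inertia_weight(t, T, sched.wmax, sched.wmin)
    c1, c2 = accel_coefficients(t, T, sched)
    if counters is None:
        counters = {}
    for key in ("branch_late", "branch_mid", "branch_early", "levy_sweeps", "restarts"):
        counters.setdefault(key, 0)

    # elite snapshot (by personal-best score) before any modification
    order = np.argsort(state.pbest_scores)[::-1]
    elite_idx = order[: sched.elite_count]
    elite_positions = state.pbest_positions[elite_idx].copy()
    elite_scores = state.pbest_scores[elite_idx].copy()
    ranked_pos = state.pbest_positions[order[:3]].copy()
    ranked_scores = state.pbest_scores[order[:3]].copy()

    lo_mid, hi_mid = sched.mid_perturb_range
    lo_early, hi_early = sched.early_perturb_range
    for i in range(Np):
        x = state.positions[i]
        if t > sched.late_phase_frac * T:
            counters["branch_late"] += 1
            if rng.random() < 0.5:
                n_swap = min(k, sched.gene_swap_count)
                genes = rng.choice(k, size=n_swap, replace=False)
                x = x.copy()
                x[genes] = state.gbest_position[genes]
            else:
                x = x + levy_step(k, sched.levy_beta, rng, sched.levy_scale)
        elif t > sched.mid_phase_frac * T:
            counters["branch_mid"] += 1
            influence = state.gbest_position - x
            perturb = rng.integers(lo_mid, hi_mid + 1, size=k)
            exploration_factor = 2.0 - 2.0 * t / T
            x = x + sched.mid_influence * influence + exploration_factor * perturb
        else:
            counters["branch_early"] += 1
            if rng.random() < 0.5:
                leader = select_leader(
                    ranked_pos, ranked_scores, 1.0, state.pbest_positions, rng
                )
                x, v = hybrid_velocity_update(
                    x, state.velocities[i], leader, state.gbest_position, w, c1, c2, rng
                )
                state.velocities[i] = v
            else:
                x = x + rng.integers(lo_early, hi_early + 1, size=k)
        state.positions[i] = x

    if t % sched.levy_period == 0:
        counters["levy_sweeps"] += 1
        for i in range(Np):
            state.positions[i] = state.positions[i] + levy_step(
                k, sched.levy_beta, rng, sched.levy_scale
            )

    stagnant = state.no_improve >= sched.restart_threshold
    for i in np.nonzero(stagnant)[0]:
        counters["restarts"] += 1
        state.positions[i] = rng.uniform(0, D - 1, size=k)
        state.no_improve[i] = 0

    np.clip(state.positions, 0, D - 1, out=state.positions)
    decoded = _decode_all(state.positions, D, rng)
    scores = evaluator.score_many(decoded)
    _update_bests(state, state.positions, decoded, scores)

    # worst particle inherits the global best
    worst = int(np.argmin(state.pbest_scores))
    state.positions[worst] = state.gbest_position.copy()
    state.pbest_positions[worst] = state.gbest_position.copy()
    state.pbest_scores[worst] = state.gbest_score
    state.velocities[worst] = 0.0
    state.no_improve[worst] = 0

    # re-insert pre-update elites over the worst remaining slots if lost
    for pos, score in zip(elite_positions, elite_scores):
        survives = np.any(
            np.all(state.pbest_positions == pos, axis=1)
            & (state.pbest_scores >= score)
        )
        if survives:
            continue
        slot = int(np.argmin(state.pbest_scores))
        if state.pbest_scores[slot] < score:
            state.positions[slot] = pos.copy()
            state.pbest_positions[slot] = pos.copy()
            state.pbest_scores[slot] = score
            state.velocities[slot] = 0.0
            state.no_improve[slot] = 0

    state.iteration += 1
    state.curve.append(state.gbest_score)
    return state


def hybrid_run(
    table: DrugTable,
    k: int,
    seed: int,
    n_particles: int = 30,
    n_iter: int = 500,
    weights: CriterionWeights | None = None,
    sched: HybridSchedule | None = None,
    lambda1: float = 1.0,
    lambda2: float = 1.0,
    evaluator: Evaluator | None = None,
) -> OptimizerResult:
    """Full hybrid run: opposition init, then T phase-switched iterations.

    Deterministic for a fixed (table, config, seed): a single seeded generator
    drives every stochastic draw in a fixed order.  ``extras`` carries branch
    execution counters and the restart count.
    """
    if n_particles < 3:
        raise ValueError("the hybrid needs a population of at least 3")
    sched = sched or HybridSchedule()
    rng = np.random.default_rng(seed)
    ev = evaluator or Evaluator(table, weights, lambda1, lambda2)
    state = opposition_init(ev, k, n_particles, rng, n_iter)
    n_init = ev.n_evals
    counters: dict = {}
    for _ in range(n_iter):
        hybrid_step(state, ev, rng, sched, counters)
    sel = SelectionVector(state.gbest_position.astype(int), k)
    return OptimizerResult(
        selection=sel,
        score=state.gbest_score,
        curve=np.asarray(state.curve),
        n_evals_total=ev.n_evals,
        n_evals_init=n_init,
        n_evals_iter=ev.n_evals - n_init,
        extras=counters,
    )
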