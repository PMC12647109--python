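"""Baseline optimizers: standard PSO and the enhanced vulture algorithm (EAVOA).

Both operate on real-valued positions of length ``k`` over the decode contract
of :mod:`drugswarm.objective` (round / clamp / de-duplicate), so every
evaluated candidate is a feasible subset of drug indices.

EAVOA models vulture foraging: a time-decaying stochastic *starvation rate* F
switches each individual between a global exploration move (|F| >= 1), an
elite-aggregation move SAM (0.5 <= |F| < 1), and a spiral exploitation move
RFS (|F| < 0.5), with the leader drawn probabilistically from the best three
individuals (RVSS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from drugswarm.data import DrugTable
from drugswarm.objective import CriterionWeights, Evaluator, SelectionVector, repair

__all__ = [
    "SwarmState",
    "OptimizerResult",
    "inertia_weight",
    "pso_step",
    "pso_run",
    "starvation_rate",
    "rvss_thresholds",
    "select_leader",
    "rotating_flight",
    "accumulation_move",
    "eavoa_step",
    "eavoa_run",
]


@dataclass
class SwarmState:
    """Array-of-particles swarm state shared by all optimizers.

    ``positions`` are real vectors; ``pbest_positions`` hold the (decoded,
    float-cast) best selection each particle has reached, ``pbest_scores`` the
    corresponding penalized fitness.  ``curve`` records the global best after
    every iteration and is non-decreasing by construction.
    """

    positions: np.ndarray
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_scores: np.ndarray
    gbest_position: np.ndarray
    gbest_score: float
    no_improve: np.ndarray
    iteration: int
    max_iteration: int
    curve: list[float] = field(default_factory=list)

    @property
    def n_particles(self) -> int:
        return len(self.positions)


@dataclass
class OptimizerResult:
    """Outcome of one optimizer run."""

    selection: SelectionVector
    score: float
    curve: np.ndarray
    n_evals_total: int
    n_evals_init: int
    n_evals_iter: int
    extras: dict = field(default_factory=dict)


def _decode_all(positions: np.ndarray, n_drugs: int, rng: np.random.Generator) -> np.ndarray:
    return np.stack([repair(p, n_drugs, rng) for p in positions])


def _random_init(
    evaluator: Evaluator, k: int, n_particles: int, rng: np.random.Generator, T: int
) -> SwarmState:
    """Uniform random positions in [0, D-1]^k with zero velocities."""
    D = evaluator.n_drugs
    positions = rng.uniform(0, D - 1, size=(n_particles, k))
    decoded = _decode_all(positions, D, rng)
    scores = evaluator.score_many(decoded)
    best = int(np.argmax(scores))
    return SwarmState(
        positions=positions,
        velocities=np.zeros_like(positions),
        pbest_positions=decoded.astype(float),
        pbest_scores=scores.copy(),
        gbest_position=decoded[best].astype(float),
        gbest_score=float(scores[best]),
        no_improve=np.zeros(n_particles, dtype=int),
        iteration=0,
        max_iteration=T,
    )


def _update_bests(
    state: SwarmState, positions: np.ndarray, decoded: np.ndarray, scores: np.ndarray
) -> None:
    """Strict-improvement personal/global best updates plus stagnation counters."""
    improved = scores > state.pbest_scores
    state.pbest_scores = np.where(improved, scores, state.pbest_scores)
    state.pbest_positions[improved] = decoded[improved].astype(float)
    state.no_improve = np.where(improved, 0, state.no_improve + 1)
    best = int(np.argmax(state.pbest_scores))
    if state.pbest_scores[best] > state.gbest_score:
        state.gbest_score = float(state.pbest_scores[best])
        state.gbest_position = state.pbest_positions[best].copy()


# --------------------------------------------------------------------------
# PSO
# --------------------------------------------------------------------------

def inertia_weight(t: int, T: int, wmax: float = 0.9, wmin: float = 0.4) -> float:
    """Linearly decaying inertia weight: wmax at t=0 down to wmin at t=T."""
    if T < 1:
        raise ValueError("max iteration T must be >= 1")
    if not 0 <= t <= T:
        raise ValueError(f"iteration t={t} outside [0, {T}]")
    return wmax - (wmax - wmin) * t / T


def pso_step(
    state: SwarmState,
    evaluator: Evaluator,
    rng: np.random.Generator,
    c1: float = 2.0,
    c2: float = 2.0,
    wmax: float = 0.9,
    wmin: float = 0.4,
) -> SwarmState:
    """One synchronous PSO iteration: velocity/position update, decode, evaluate."""
    w = inertia_weight(state.iteration, state.max_iteration, wmax, wmin)
    shape = state.positions.shape
    r1 = rng.random(shape)
    r2 = rng.random(shape)
    state.velocities = (
        w * state.velocities
        + c1 * r1 * (state.pbest_positions - state.positions)
        + c2 * r2 * (state.gbest_position - state.positions)
    )
    state.positions = state.positions + state.velocities
    decoded = _decode_all(state.positions, evaluator.n_drugs, rng)
    scores = evaluator.score_many(decoded)
    _update_bests(state, state.positions, decoded, scores)
    state.iteration += 1
    state.curve.append(state.gbest_score)
    return state


def pso_run(
    table: DrugTable,
    k: int,
    seed: int,
    n_particles: int = 30,
    n_iter: int = 500,
    weights: CriterionWeights | None = None,
    c1: float = 2.0,
    c2: float = 2.0,
    lambda1: float = 1.0,
    lambda2: float = 1.0,
    evaluator: Evaluator | None = None,
) -> OptimizerResult:
    """Full standard-PSO run; deterministic for a fixed (table, config, seed)."""
    rng = np.random.default_rng(seed)
    ev = evaluator or Evaluator(table, weights, lambda1, lambda2)
    state = _random_init(ev, k, n_particles, rng, n_iter)
    n_init = ev.n_evals
    for _ in range(n_iter):
        pso_step(state, ev, rng, c1=c1, c2=c2)
    sel = SelectionVector(state.gbest_position.astype(int), k)
    return OptimizerResult(
        selection=sel,
        score=state.gbest_score,
        curve=np.asarray(state.curve),
        n_evals_total=ev.n_evals,
        n_evals_init=n_init,
        n_evals_iter=ev.n_evals - n_init,
    )


# --------------------------------------------------------------------------
# EAVOA
# --------------------------------------------------------------------------

def starvation_rate(t: int, T: int, h: float, rng: np.random.Generator) -> float:
    """Stochastic starvation rate F driving the exploration/exploitation switch.

    F = (2*rand + 1) * z * (1 - t/T) + dt with rand ~ U(0,1), z ~ U(-1,1) and
    the disturbance dt = h * (sin(pi t / 2T) + cos(pi t / 2T) - 1), which is 0
    exactly at both t=0 and t=T.
    """
    if not 0 <= t <= T:
        raise ValueError(f"iteration t={t} outside [0, {T}]")
    rand = rng.random()
    z = rng.uniform(-1.0, 1.0)
    dt = h * (math.sin(math.pi * t / (2 * T)) + math.cos(math.pi * t / (2 * T)) - 1.0)
    return (2.0 * rand + 1.0) * z * (1.0 - t / T) + dt


def rvss_thresholds(
    best3_scores: np.ndarray, weighting: str = "proportional"
) -> tuple[float, float]:
    """Leader-selection thresholds (w1, w2) from the top-3 fitness values.

    ``proportional`` (default): shares of fitness shifted to be positive, so
    better leaders are chosen more often; equal fitnesses give w1 = w2 = 1/3.
    ``inverse``: the literal inverse-fitness transcription, retained for
    comparison (sensible only when fitness is positive).
    """
    f = np.asarray(best3_scores, dtype=float)
    if len(f) != 3:
        raise ValueError("exactly three leader fitness values expected")
    shifted = f - f.min() + 1e-9
    if weighting == "proportional":
        shares = shifted / shifted.sum()
    elif weighting == "inverse":
        inv = 1.0 / shifted
        shares = np.array([inv[1], inv[0], inv[2]]) / inv.sum()
    else:
        raise ValueError(f"unknown rvss weighting {weighting!r}")
    return float(shares[0]), float(shares[1])


def select_leader(
    ranked_positions: np.ndarray,
    ranked_scores: np.ndarray,
    F: float,
    population: np.ndarray,
    rng: np.random.Generator,
    weighting: str = "proportional",
    thresholds: tuple[float, float] | None = None,
) -> np.ndarray:
    """RVSS: pick BestVulture1, BestVulture2, or a random individual.

    The draw p = rand * |F| is compared against the thresholds (w1, w2); a
    starving population (large |F|) therefore falls back to random individuals
    more often, sustaining exploration.  With fewer than 3 ranked leaders the
    best individual is returned.
    """
    if len(ranked_positions) < 3:
        return ranked_positions[0]
    w1, w2 = thresholds if thresholds is not None else rvss_thresholds(
        ranked_scores[:3], weighting
    )
    p = rng.random() * abs(F)
    if p < w1:
        return ranked_positions[0]
    if p < w1 + w2:
        return ranked_positions[1]
    return population[rng.integers(len(population))]


_TRIG_CLIP = 10.0 * math.pi


def rotating_flight(
    R: np.ndarray,
    P: np.ndarray,
    F: float,
    rng: np.random.Generator,
    trig: str = "literal",
) -> tuple[np.ndarray, np.ndarray]:
    """RFS spiral candidates B1, B2 around the leader R.

    S1 and S2 scale the displacement (R - P) by F and a cos/sin factor whose
    argument is the elementwise product 2*P*R clipped to +-10*pi (``literal``),
    or 2*pi*u with u ~ U(0,1) per dimension (``random``).  Each candidate gets
    an independent uniformly random +- sign.  The caller greedily keeps the
    fitter decoded candidate.
    """
    if trig == "literal":
        arg = np.clip(2.0 * P * R, -_TRIG_CLIP, _TRIG_CLIP)
    elif trig == "random":
        arg = 2.0 * math.pi * rng.random(len(R))
    else:
        raise ValueError(f"unknown rfs trig mode {trig!r}")
    s1 = rng.random() * ((R - P) * F * np.cos(arg))
    s2 = rng.random() * ((R - P) * F * np.sin(arg))
    sign1 = 1.0 if rng.random() < 0.5 else -1.0
    sign2 = 1.0 if rng.random() < 0.5 else -1.0
    return R + sign1 * s1, R + sign2 * s2


def accumulation_move(
    best3_positions: np.ndarray,
    R: np.ndarray,
    P: np.ndarray,
    F: float,
    sam_form: str = "symmetrized",
    eps: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """SAM aggregation candidates C4 = (C1+C2)/2 and C5 = (C1+C3)/2.

    Each elite-derived point C_m pulls the elite BestVulture_m toward the
    current individual with a distance-weighted correction scaled by F.  The
    default ``symmetrized`` form uses C_m = BV_m - (BV_m*x) / ((BV_m - x)^2 +
    eps) * F elementwise with x = P; coordinates where BV_m == x contribute no
    correction (the vanishing-displacement limit), so a fully converged swarm
    is a fixed point.  ``literal`` keeps the printed transcription, which
    mixes R and P and reuses BestVulture2 inside C3.
    """
    bv1, bv2, bv3 = np.asarray(best3_positions, dtype=float)

    def corr(bv: np.ndarray, num_x: np.ndarray, den_x: np.ndarray) -> np.ndarray:
        diff = bv - den_x
        return np.where(diff == 0.0, 0.0, bv * num_x / (diff**2 + eps) * F)

    if sam_form == "symmetrized":
        c1 = bv1 - corr(bv1, P, P)
        c2 = bv2 - corr(bv2, P, P)
        c3 = bv3 - corr(bv3, P, P)
    elif sam_form == "literal":
        c1 = bv1 - corr(bv1, R, R)
        c2 = bv2 - corr(bv2, P, R)
        c3 = bv3 - corr(bv2, P, R)
    else:
        raise ValueError(f"unknown sam form {sam_form!r}")
    return (c1 + c2) / 2.0, (c1 + c3) / 2.0


def eavoa_step(
    state: SwarmState,
    evaluator: Evaluator,
    rng: np.random.Generator,
    h: float = 0.5,
    rvss_weighting: str = "proportional",
    sam_form: str = "symmetrized",
    rfs_trig: str = "literal",
) -> SwarmState:
    """One EAVOA iteration over the whole swarm.

    Per individual: draw F; pick a leader by RVSS; move by the exploration
    rule (|F| >= 1), SAM (0.5 <= |F| < 1) or RFS (|F| < 0.5); decode and keep
    the fitter where the move produces two candidates.
    """
    D = evaluator.n_drugs
    k = state.positions.shape[1]
    t, T = state.iteration, state.max_iteration
    order = np.argsort(state.pbest_scores)[::-1]
    ranked_pos = state.pbest_positions[order[:3]]
    ranked_scores = state.pbest_scores[order[:3]]

    new_positions = np.empty_like(state.positions)
    decoded = np.empty((state.n_particles, k), dtype=int)
    scores = np.empty(state.n_particles)
    for i in range(state.n_particles):
        P = state.positions[i]
        F = starvation_rate(t, T, h, rng)
        R = select_leader(
            ranked_pos, ranked_scores, F, state.pbest_positions, rng, rvss_weighting
        )
        if abs(F) >= 1.0:
            # exploration move from the base vulture algorithm (not printed in
            # the enhanced variant): dive toward the leader or scatter.
            if rng.random() < 0.5:
                cand = R - np.abs(2.0 * rng.random(k) * R - P) * F
            else:
                cand = rng.uniform(0, D - 1, size=k)
            candidates = cand[None, :]
        elif abs(F) >= 0.5:
            c4, c5 = accumulation_move(ranked_pos, R, P, F, sam_form)
            candidates = np.stack([c4, c5])
        else:
            b1, b2 = rotating_flight(R, P, F, rng, rfs_trig)
            candidates = np.stack([b1, b2])

        cand_decoded = _decode_all(candidates, D, rng)
        cand_scores = evaluator.score_many(cand_decoded)
        best = int(np.argmax(cand_scores))
        new_positions[i] = candidates[best]
        decoded[i] = cand_decoded[best]
        scores[i] = cand_scores[best]

    state.positions = new_positions
    _update_bests(state, new_positions, decoded, scores)
    state.iteration += 1
    state.curve.append(state.gbest_score)
    return state


def eavoa_run(
    table: DrugTable,
    k: int,
    seed: int,
    n_particles: int = 30,
    n_iter: int = 500,
    weights: CriterionWeights | None = None,
    h: float = 0.5,
    lambda1: float = 1.0,
    lambda2: float = 1.0,
    rvss_weighting: str = "proportional",
    sam_form: str = "symmetrized",
    rfs_trig: str = "literal",
    evaluator: Evaluator | None = None,
) -> OptimizerResult:
    """Full EAVOA run; deterministic for a fixed (table, config, seed)."""
    if n_particles < 3:
        raise ValueError("EAVOA needs a population of at least 3")
    rng = np.random.default_rng(seed)
    ev = evaluator or Evaluator(table, weights, lambda1, lambda2)
    state = _random_init(ev, k, n_particles, rng, n_iter)
    n_init = ev.n_evals
    for _ in range(n_iter):
        eavoa_step(
            state, ev, rng, h=h, rvss_weighting=rvss_weighting,
            sam_form=sam_form, rfs_trig=rfs_trig,
        )
    sel = SelectionVector(state.gbest_position.astype(int), k)
    return OptimizerResult(
        selection=sel,
        score=state.gbest_score,
        curve=np.asarray(state.curve),
        n_evals_total=ev.n_evals,
        n_evals_init=n_init,
        n_evals_iter=ev.n_evals - n_init,
    )
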