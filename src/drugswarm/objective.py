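"""Decision encoding, weighted-sum fitness, constraints, penalties and repair.

A candidate solution is a vector of ``k`` distinct drug indices drawn from
``[0, D)``.  Optimizers move real-valued positions of length ``k``; the decode
contract (round, clamp, de-duplicate) maps any real vector to a feasible
selection.  The objective is the weighted sum

    f(x) = alpha * mean(rating_norm) - beta * mean(severity_norm)
         + gamma * mean(reviews_norm)

over the selected records, and infeasible selections are penalized by
violation counts:  f_pen = f - lambda1 * P_equality - lambda2 * P_uniqueness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from drugswarm.data import DrugTable

__all__ = [
    "CriterionWeights",
    "SelectionVector",
    "FitnessResult",
    "Evaluator",
    "fitness",
    "penalize",
    "repair",
    "is_feasible",
    "brute_force_optimum",
]


@dataclass(frozen=True)
class CriterionWeights:
    """Non-negative weights trading off rating (alpha), side-effect severity
    (beta, subtracted) and review consensus (gamma).  Defaults are the base
    configuration alpha=0.5, beta=0.3, gamma=0.2."""

    alpha: float = 0.5
    beta: float = 0.3
    gamma: float = 0.2

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class SelectionVector:
    """An ordered list of drug indices with a target subset size ``k``."""

    indices: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)

    def is_feasible(self, n_drugs: int) -> bool:
        idx = self.indices
        return (
            len(idx) == self.k
            and bool(np.all((idx >= 0) & (idx < n_drugs)))
            and len(set(idx.tolist())) == len(idx)
        )


@dataclass
class FitnessResult:
    """Per-criterion means, violation counts, and raw/penalized fitness."""

    mean_rating: float
    mean_side_effect: float
    mean_reviews: float
    raw_fitness: float
    p_equality: int = 0
    p_uniqueness: int = 0
    penalized_fitness: float = 0.0


def is_feasible(indices: np.ndarray, k: int, n_drugs: int) -> bool:
    """Exact-size, in-bounds, all-distinct feasibility predicate."""
    return SelectionVector(indices, k).is_feasible(n_drugs)


def fitness(sel: SelectionVector, table: DrugTable, wts: CriterionWeights) -> FitnessResult:
    """Raw weighted-sum fitness of a selection (no penalties applied here).

    Out-of-range indices never crash: they are clamped into [0, D) for the
    component means and left for :func:`penalize` to count as violations.
    """
    rating, severity, reviews = table.criteria_arrays()
    idx = np.clip(sel.indices, 0, table.n_drugs - 1)
    mr = float(rating[idx].mean())
    ms = float(severity[idx].mean())
    mv = float(reviews[idx].mean())
    raw = wts.alpha * mr - wts.beta * ms + wts.gamma * mv
    return FitnessResult(mr, ms, mv, raw, penalized_fitness=raw)


def penalize(
    sel: SelectionVector,
    fit: FitnessResult,
    lambda1: float,
    lambda2: float,
    n_drugs: int,
) -> FitnessResult:
    """Subtract violation-count penalties from the raw fitness.

    P_equality = |len(sel) - k| + number of out-of-bounds indices;
    P_uniqueness = number of duplicate entries.  Feasible selections are left
    untouched (penalized == raw).
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalty coefficients must be >= 0")
    idx = sel.indices
    out_of_bounds = int(np.count_nonzero((idx < 0) | (idx >= n_drugs)))
    fit.p_equality = abs(len(idx) - sel.k) + out_of_bounds
    fit.p_uniqueness = len(idx) - len(set(idx.tolist()))
    fit.penalized_fitness = (
        fit.raw_fitness - lambda1 * fit.p_equality - lambda2 * fit.p_uniqueness
    )
    return fit


def repair(
    raw_position: np.ndarray, n_drugs: int, rng: np.random.Generator
) -> np.ndarray:
    """Decode a real position into a feasible index vector.

    Coordinates are rounded to the nearest integer and clamped to
    ``[0, n_drugs - 1]``; duplicates are then replaced, scanning left to
    right, by a uniformly random unused index.  Identity on already-feasible
    integer positions.
    """
    k = len(raw_position)
    if n_drugs < k:
        raise ValueError(f"cannot select {k} unique indices from {n_drugs} drugs")
    idx = np.clip(np.rint(np.asarray(raw_position, dtype=float)), 0, n_drugs - 1).astype(int)
    seen: set[int] = set()
    dup_slots = []
    for j, v in enumerate(idx):
        if v in seen:
            dup_slots.append(j)
        else:
            seen.add(int(v))
    if dup_slots:
        unused = np.array([v for v in range(n_drugs) if v not in seen], dtype=int)
        replacement = rng.choice(unused, size=len(dup_slots), replace=False)
        idx[dup_slots] = replacement
    return idx


class Evaluator:
    """Vectorized penalized-fitness evaluation with bookkeeping counters.

    Wraps a normalized table, criterion weights and penalty coefficients.
    All optimizers route their evaluations through an Evaluator so that
    (a) the evaluation count is a countable complexity contract and
    (b) feasibility of every decoded candidate can be asserted in tests.
    """

    def __init__(
        self,
        table: DrugTable,
        weights: CriterionWeights | None = None,
        lambda1: float = 1.0,
        lambda2: float = 1.0,
        check_feasible: bool = False,
    ) -> None:
        if lambda1 < 0 or lambda2 < 0:
            raise ValueError("penalty coefficients must be >= 0")
        self.table = table
        self.weights = weights or CriterionWeights()
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.check_feasible = check_feasible
        self.n_drugs = table.n_drugs
        self._rating, self._severity, self._reviews = table.criteria_arrays()
        self.n_evals = 0
        self.n_infeasible_seen = 0

    def score_one(self, indices: np.ndarray, k: int | None = None) -> float:
        """Penalized fitness of one index vector (feasible fast path)."""
        return float(self.score_many(np.asarray(indices, dtype=int)[None, :], k=k)[0])

    def score_many(self, idx_matrix: np.ndarray, k: int | None = None) -> np.ndarray:
        """Penalized fitness of each row of an (n, k) index matrix."""
        idx_matrix = np.asarray(idx_matrix, dtype=int)
        n, width = idx_matrix.shape
        k = width if k is None else k
        self.n_evals += n

        clipped = np.clip(idx_matrix, 0, self.n_drugs - 1)
        w = self.weights
        raw = (
            w.alpha * self._rating[clipped].mean(axis=1)
            - w.beta * self._severity[clipped].mean(axis=1)
            + w.gamma * self._reviews[clipped].mean(axis=1)
        )
        oob = ((idx_matrix < 0) | (idx_matrix >= self.n_drugs)).sum(axis=1)
        sorted_idx = np.sort(idx_matrix, axis=1)
        dups = (sorted_idx[:, 1:] == sorted_idx[:, :-1]).sum(axis=1)
        p_eq = np.abs(width - k) + oob
        infeasible = (p_eq > 0) | (dups > 0)
        self.n_infeasible_seen += int(np.count_nonzero(infeasible))
        if self.check_feasible and np.any(infeasible):
            raise AssertionError("infeasible candidate reached the evaluator")
        return raw - self.lambda1 * p_eq - self.lambda2 * dups

    def evaluate(self, sel: SelectionVector) -> FitnessResult:
        """Full :class:`FitnessResult` for one selection (penalty path)."""
        fit = fitness(sel, self.table, self.weights)
        return penalize(fit=fit, sel=sel, lambda1=self.lambda1, lambda2=self.lambda2,
                        n_drugs=self.n_drugs)


def brute_force_optimum(
    table: DrugTable,
    k: int,
    wts: CriterionWeights | None = None,
    budget: int = 10**6,
) -> tuple[SelectionVector, float]:
    """Enumerate all k-subsets and return the raw-fitness argmax.

    The test oracle for small instances.  Ties break toward the
    lexicographically smallest index vector (``combinations`` emits subsets in
    lexicographic order and only strict improvements replace the incumbent).
    """
    wts = wts or CriterionWeights()
    n = table.n_drugs
    n_subsets = comb(n, k)
    if n_subsets > budget:
        raise ValueError(
            f"C({n},{k}) = {n_subsets} exceeds the enumeration budget {budget}"
        )
    rating, severity, reviews = table.criteria_arrays()
    per_drug = wts.alpha * rating - wts.beta * severity + wts.gamma * reviews
    best_idx: tuple[int, ...] | None = None
    best_val = -np.inf
    for subset in combinations(range(n), k):
        val = per_drug[list(subset)].mean()
        if val > best_val:
            best_val = val
            best_idx = subset
    assert best_idx is not None
    return SelectionVector(np.array(best_idx), k), float(best_val)
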