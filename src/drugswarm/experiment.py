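"""Multi-run benchmarking and weight-sensitivity analysis.

Runs each optimizer across a common seed ladder, summarizes final fitness
(mean, sample std, max), ranks algorithms by a composite weighted score, and
probes the criterion weights (alpha, beta, gamma) four ways: one-way sweeps,
a simplex grid at fixed step, Sobol variance decomposition (Saltelli
estimators over Sobol quasirandom samples), and Kruskal-Wallis comparison of
configuration groups.

The "weighted score" composite 0.5*mean + 0.3*max + 0.2*(1 - std) rewards
average quality, peak quality and run-to-run stability; it is an explicit
package convention (configurable via ``score_weights``), not a quantity with
a canonical definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.stats import qmc

from drugswarm.baselines import OptimizerResult, eavoa_run, pso_run
from drugswarm.data import DrugTable
from drugswarm.hybrid import hybrid_run
from drugswarm.objective import CriterionWeights

__all__ = [
    "ALGORITHMS",
    "BenchmarkSummary",
    "SensitivityResult",
    "run_benchmark",
    "one_way_sweep",
    "simplex_grid",
    "sobol_indices",
    "kruskal_wallis",
    "anova",
    "selection_frequencies",
    "top_k_overlap",
    "export_run_artifacts",
]

ALGORITHMS: dict[str, Callable[..., OptimizerResult]] = {
    "pso": pso_run,
    "eavoa": eavoa_run,
    "hybrid": hybrid_run,
}

DEFAULT_SCORE_WEIGHTS = (0.5, 0.3, 0.2)  # on (mean, max, 1 - std)


@dataclass
class BenchmarkSummary:
    """Per-algorithm multi-run statistics plus composite score and rank."""

    algorithm: str
    runs: list[float]
    mean: float
    std: float
    max: float
    weighted_score: float
    rank: int = 0
    results: list[OptimizerResult] = field(default_factory=list, repr=False)


@dataclass
class SensitivityResult:
    """Container for the weight-sensitivity outputs (filled per analysis mode)."""

    one_way: list[tuple[float, float, float]] | None = None
    grid: list[tuple[float, float, float, float]] | None = None
    sobol: dict[str, tuple[float, float]] | None = None
    comparison: tuple[float, float] | None = None


def _summarize(
    algorithm: str,
    results: list[OptimizerResult],
    score_weights: tuple[float, float, float],
) -> BenchmarkSummary:
    finals = [r.score for r in results]
    mean = float(np.mean(finals))
    std = float(np.std(finals, ddof=1)) if len(finals) > 1 else 0.0
    mx = float(np.max(finals))
    a, b, c = score_weights
    return BenchmarkSummary(
        algorithm=algorithm,
        runs=finals,
        mean=mean,
        std=std,
        max=mx,
        weighted_score=a * mean + b * mx + c * (1.0 - std),
        results=results,
    )


def run_benchmark(
    table: DrugTable,
    algorithms: Sequence[str],
    n_runs: int,
    k: int,
    base_seed: int,
    n_particles: int = 30,
    n_iter: int = 500,
    weights: CriterionWeights | None = None,
    score_weights: tuple[float, float, float] = DEFAULT_SCORE_WEIGHTS,
    **run_kwargs,
) -> list[BenchmarkSummary]:
    """Run each algorithm over the common seed ladder base_seed..base_seed+n-1.

    Using the same seeds per run index across algorithms makes the comparison
    paired.  Ranks are assigned by weighted score descending, ties broken by
    algorithm name.
    """
    unknown = [a for a in algorithms if a not in ALGORITHMS]
    if unknown:
        raise ValueError(
            f"unknown algorithm(s) {unknown}; valid names: {sorted(ALGORITHMS)}"
        )
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 for mean/std reporting")
    summaries = []
    for name in algorithms:
        runner = ALGORITHMS[name]
        results = [
            runner(
                table, k=k, seed=base_seed + r, n_particles=n_particles,
                n_iter=n_iter, weights=weights, **run_kwargs,
            )
            for r in range(n_runs)
        ]
        summaries.append(_summarize(name, results, score_weights))
    ordered = sorted(summaries, key=lambda s: (-s.weighted_score, s.algorithm))
    for rank, s in enumerate(ordered, start=1):
        s.rank = rank
    return summaries


def one_way_sweep(
    table: DrugTable,
    coefficient: str,
    values: Sequence[float],
    n_runs: int,
    k: int,
    base_seed: int,
    base_weights: CriterionWeights | None = None,
    n_particles: int = 30,
    n_iter: int = 500,
) -> list[tuple[float, float, float]]:
    """Vary one of alpha/beta/gamma over ``values``, others at their base.

    Returns (value, mean final hybrid fitness, sample std) per grid point,
    using the same seed ladder at every point so rows are paired.
    """
    if coefficient not in ("alpha", "beta", "gamma"):
        raise ValueError("coefficient must be one of alpha, beta, gamma")
    base = base_weights or CriterionWeights()
    rows = []
    for value in values:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"sweep value {value} outside [0, 1]")
        wts = CriterionWeights(**{**base.__dict__, coefficient: float(value)})
        finals = [
            hybrid_run(
                table, k=k, seed=base_seed + r, n_particles=n_particles,
                n_iter=n_iter, weights=wts,
            ).score
            for r in range(n_runs)
        ]
        std = float(np.std(finals, ddof=1)) if len(finals) > 1 else 0.0
        rows.append((float(value), float(np.mean(finals)), std))
    return rows


def simplex_grid(step: float) -> list[tuple[float, float, float]]:
    """All non-negative (alpha, beta, gamma) on the step lattice with sum 1.

    step=0.1 yields the 66 = C(12, 2) stars-and-bars triples.
    """
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-9:
        raise ValueError(f"step {step} does not divide 1")
    return [
        (i / n, j / n, (n - i - j) / n)
        for i in range(n + 1)
        for j in range(n + 1 - i)
    ]


def sobol_indices(
    objective_fn: Callable[[float, float, float], float],
    n_base: int,
    seed: int,
    names: tuple[str, ...] = ("alpha", "beta", "gamma"),
) -> dict[str, tuple[float, float]]:
    """First-order and total Sobol indices via Saltelli A/B/AB_i estimators.

    Samples the unit cube of the three coefficients with a scrambled Sobol
    sequence; S_i = E[f_B (f_ABi - f_A)] / Var, ST_i = E[(f_A - f_ABi)^2] /
    (2 Var).  A degenerate (constant) objective returns all-zero indices.
    """
    if n_base < 64:
        raise ValueError("n_base must be >= 64 (a power of 2 is recommended)")
    d = len(names)
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
    m = sampler.random(n_base)
    A, B = m[:, :d], m[:, d:]

    def apply(mat: np.ndarray) -> np.ndarray:
        return np.array([objective_fn(*row) for row in mat], dtype=float)

    fA, fB = apply(A), apply(B)
    var = float(np.var(np.concatenate([fA, fB])))
    out: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(names):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fABi = apply(ABi)
        if var <= 1e-30:
            out[name] = (0.0, 0.0)
            continue
        s_i = float(np.mean(fB * (fABi - fA)) / var)
        st_i = float(0.5 * np.mean((fA - fABi) ** 2) / var)
        out[name] = (s_i, st_i)
    return out


def weight_objective(
    table: DrugTable,
    k: int,
    seed: int,
    n_particles: int = 20,
    n_iter: int = 100,
    n_rep: int = 1,
) -> Callable[[float, float, float], float]:
    """Objective for Sobol analysis on the real pipeline: mean hybrid final
    fitness at a fixed seed (or averaged over ``n_rep`` seeds) per weight
    triple, so optimizer noise is folded into the function."""

    def fn(alpha: float, beta: float, gamma: float) -> float:
        wts = CriterionWeights(alpha, beta, gamma)
        finals = [
            hybrid_run(
                table, k=k, seed=seed + r, n_particles=n_particles,
                n_iter=n_iter, weights=wts,
            ).score
            for r in range(n_rep)
        ]
        return float(np.mean(finals))

    return fn


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H with tie correction; chi-square p-value.

    The degenerate all-identical case (undefined tie correction) returns
    (H=0, p=1): no rank separation, no evidence of a difference.
    """
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way ANOVA F and p, offered alongside the distribution-free default."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def selection_frequencies(results: Sequence[OptimizerResult], n_drugs: int) -> np.ndarray:
    """Per-drug selection frequency across a set of runs."""
    counts = np.zeros(n_drugs)
    for r in results:
        counts[r.selection.indices] += 1
    return counts / max(len(results), 1)


def top_k_overlap(freq_a: np.ndarray, freq_b: np.ndarray, top: int = 10) -> float:
    """|top(config) ∩ top(base)| / top over drugs ranked by selection frequency."""
    top_a = set(np.argsort(freq_a)[::-1][:top].tolist())
    top_b = set(np.argsort(freq_b)[::-1][:top].tolist())
    return len(top_a & top_b) / top


def export_run_artifacts(
    summaries: Sequence[BenchmarkSummary],
    curves: dict[str, Sequence[np.ndarray]],
    outdir: str | Path,
) -> list[Path]:
    """Write convergence TSVs, a box-plot CSV, and the summary table CSV.

    Convergence files (one per algorithm, mean curve across its runs) are
    two-column ``iteration<TAB>best_score``; the box-plot CSV holds one column
    per algorithm and one row per run; the summary CSV mirrors the runs-by-
    algorithms layout with Mean / Std. Dev / Max Fitness / Weighted Score /
    Final Rank footer rows.  Deterministic: identical inputs produce
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for name, runs in curves.items():
        mean_curve = np.mean(np.stack([np.asarray(c) for c in runs]), axis=0)
        path = outdir / f"convergence_{name}.tsv"
        lines = ["iteration\tbest_score"] + [
            f"{i}\t{v:.10g}" for i, v in enumerate(mean_curve, start=1)
        ]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(path)

    names = [s.algorithm for s in summaries]
    n_runs = max(len(s.runs) for s in summaries)
    box = outdir / "fitness_distributions.csv"
    rows = [",".join(names)]
    for r in range(n_runs):
        rows.append(
            ",".join(f"{s.runs[r]:.10g}" if r < len(s.runs) else "" for s in summaries)
        )
    box.write_text("\n".join(rows) + "\n", encoding="utf-8")
    written.append(box)

    summary = outdir / "summary.csv"
    rows = ["Run," + ",".join(names)]
    for r in range(n_runs):
        rows.append(
            f"Run {r + 1},"
            + ",".join(f"{s.runs[r]:.5f}" if r < len(s.runs) else "" for s in summaries)
        )
    rows.append("Mean," + ",".join(f"{s.mean:.5f}" for s in summaries))
    rows.append("Std. Dev," + ",".join(f"{s.std:.5f}" for s in summaries))
    rows.append("Max Fitness," + ",".join(f"{s.max:.5f}" for s in summaries))
    rows.append("Weighted Score," + ",".join(f"{s.weighted_score:.5f}" for s in summaries))
    rows.append("Final Rank," + ",".join(str(s.rank) for s in summaries))
    summary.write_text("\n".join(rows) + "\n", encoding="utf-8")
    written.append(summary)
    return written
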