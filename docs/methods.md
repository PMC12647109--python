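# Methods

This note documents the models, numerical choices and known limitations of
`drugswarm` the way a maintainer would want them written down: what each
component assumes, which constants matter, and what the test suite does and
does not demonstrate.

## Problem formulation

Drug-subset prioritization is cast as constrained single-objective
maximization over index vectors `x = [d_1, …, d_k]` of distinct drugs. The
objective is the weighted sum of three per-subset means —
`f(x) = α·mean(rating_norm) − β·mean(severity_norm) + γ·mean(reviews_norm)` —
with default weights (0.5, 0.3, 0.2). All three criteria are min-max
normalized per table, so for fully normalized inputs `f` is bounded by
`[−β, α + γ]`. We deliberately normalize the review criterion along with the
other two: leaving review counts raw would let a single heavily-reviewed drug
dominate the objective and make the fitness scale instance-dependent. A
consequence is that fitness values are comparable across tables but not
against analyses that feed raw counts into the same formula.

Constraints (exact size `k`, indices in `[0, D)`, uniqueness) are handled by
two mechanisms that cooperate:

* **repair** (the decode contract): optimizers move real vectors; decoding
  rounds to nearest integer, clamps into `[0, D−1]`, and replaces duplicates
  left-to-right with uniformly random unused indices. Every decoded
  candidate is feasible, so the search itself never leaves the feasible
  region.
* **penalties** for externally supplied selections:
  `f_pen = f − λ₁·P_equality − λ₂·P_uniqueness` where the `P` terms are
  violation *counts* (length mismatch plus out-of-bounds indices; duplicate
  count). We subtract penalties — adding them, read literally from some
  formulations, would reward violations under maximization. With criteria
  bounded by 1, the default `λ₁ = λ₂ = 1` makes any single violation strictly
  dominate any attainable criterion gain. Out-of-bounds indices are clamped
  for the component means and counted as violations, so scoring never
  crashes on malformed input.

## Side-effect severity

Severity is a lexicon-weighted mean
`S_i = Σ_j w_j f_ij / Σ_j f_ij` over term counts in the cleaned side-effect
text. Tokenization lower-cases, strips everything non-alphabetic, and
applies a small rule-based suffix lemmatizer (plural stripping only:
`-ies→-y`, `-shes/-xes/-zes/-sses → −es`, then a bare `-s` when not `-ss`).
The lemmatizer is intentionally conservative — clinical vocabulary such as
"dizziness" must survive unchanged — and its behaviour is frozen by golden
tests rather than by reference to any particular NLP toolkit.
Out-of-lexicon tokens receive `default_weight = 1` and count in the
denominator, so unknown vocabulary dilutes the score toward the mild tier
instead of being ignored. An empty text scores 0. A `token_count` metric
(raw cleaned-token count) is available as a configuration switch for users
who prefer description length over lexicon severity; severity is the
default because it is the quantity the objective is meant to minimize.

The shipped 40-term lexicon is a three-tier toy (mild=1, moderate=2,
severe=3) sufficient for testing and synthetic generation; real analyses
should supply a clinically curated `term<TAB>weight` TSV. Licensed
terminologies are not distributed with the package.

## Optimizers

All optimizers draw every stochastic decision from a single
`numpy.random.Generator` seeded per run, in a fixed documented order, so a
run is a pure function of (table, configuration, seed) and trajectories are
bit-reproducible.

**PSO.** Standard velocity/position updates with fresh `r1, r2 ~ U(0,1)` per
particle per dimension, linearly decaying inertia `w: 0.9 → 0.4`, constant
`c1 = c2 = 2.0` (a conventional choice; the acceleration constants are
otherwise unspecified for this problem), uniform random initialization in
`[0, D−1]^k` and zero initial velocities.

**EAVOA.** Each individual draws a starvation rate
`F = (2·rand + 1)·z·(1 − t/T) + dt`, `z ~ U(−1,1)` resampled per individual
per iteration, `dt = h·(sin(πt/2T) + cos(πt/2T) − 1)` with disturbance
`h = 0.5`. Phase switching follows the vulture-algorithm family convention:
`|F| ≥ 1` exploration, `0.5 ≤ |F| < 1` elite aggregation (SAM), `|F| < 0.5`
spiral exploitation (RFS). Design choices where the printed formulation is
ambiguous or inconsistent, each selectable by configuration with the listed
default:

* *RVSS thresholds* (`rvss_weighting: proportional | inverse`, default
  proportional): leader probabilities are fitness-proportional shares of the
  top three after shifting fitness to be positive, so better leaders are
  chosen more often under maximization; the inverse-fitness transcription is
  retained for comparison. Equal elite fitness yields `w₁ = w₂ = 1/3`.
* *SAM form* (`sam_form: symmetrized | literal`, default symmetrized):
  `C_m = BV_m − (BV_m·x)/((BV_m − x)² + ε)·F` elementwise with `ε = 1e−12`;
  coordinates where `BV_m = x` contribute zero correction (the vanishing-
  displacement limit), making a fully converged swarm a fixed point.
* *RFS trig argument* (`rfs_trig: literal | random`, default literal): the
  elementwise product `2·P·R` clipped to `±10π` before sin/cos; the
  alternative reads it as `2π·u`, `u ~ U(0,1)`.
* The `|F| ≥ 1` exploration move is taken from the base vulture algorithm
  (dive toward the leader `x ← R − |2·rand·R − x|·F` with probability 0.5,
  else a uniform random point in bounds), as the enhanced variant does not
  restate it.
* The `±` sign in the RFS candidates is drawn uniformly per candidate.

RFS and SAM each evaluate two decoded candidates and keep the fitter
(greedy), so EAVOA's evaluation count is linear in `Np·T` in expectation but
not an exact multiple of it.

**Hybrid PSO–EAVOA.** The package's centerpiece. Initialization is
opposition-based: `Np` uniform positions plus their coordinate-wise mirrors
`(D−1) − x` are all evaluated and the best `Np` kept. Each iteration then
applies exactly one phase branch per particle:

* `t > 0.7 T` (late): with probability 0.5 copy 2 randomly chosen genes from
  the global best, otherwise add a Lévy-flight perturbation;
* `0.4 T < t ≤ 0.7 T` (mid): `x ← x + 0.7·(gbest − x) + (2 − 2t/T)·u` with
  `u` integer-uniform on `[−3, 3]` drawn per gene;
* `t ≤ 0.4 T` (early): with probability 0.5 a PSO velocity update whose
  personal-best attractor is replaced by a vulture leader drawn by RVSS from
  the swarm's top-3 personal bests (the swarm itself serves as the vulture
  population — no second population is maintained), otherwise
  integer-uniform `[−5, 5]` noise per gene.

Afterwards: every 20th iteration adds a Lévy mutation to every particle; any
particle whose personal best has stagnated for 6 iterations is reinitialized
uniformly at random (the counter compares against its own personal best);
positions are clamped to `[0, D−1]` before decoding; the worst particle is
replaced by the global best; and the top-2 pre-update elites are re-inserted
over the worst slots if their scores would otherwise be lost. The global
best can only improve, so convergence curves are non-decreasing by
construction. Acceleration coefficients are scheduled `c1 = 2.5 − 2t/T`,
`c2 = 0.5 + 2t/T` (their sum is constant at 3), inertia as in PSO.

Lévy steps use the Mantegna construction with `β = 1.5` and unit step scale:
`step = u/|v|^{1/β}`, `u ~ N(0, σ_u²)`, `v ~ N(0,1)`, with `σ_u ≈ 0.69657`
for `β = 1.5`. The mid-phase and early-phase perturbations are drawn per
gene.

Each hybrid iteration evaluates each particle exactly once, so the
evaluation count is exactly `2·Np` (initialization) plus `Np·T`; the test
suite asserts the exact-doubling form of this `O(Np·T·D)` contract by
counter, not wall-clock.

## Benchmark harness and sensitivity analysis

`run_benchmark` runs each algorithm over the common seed ladder
`base_seed … base_seed + n_runs − 1` (pairing runs across algorithms) and
reports mean, sample standard deviation (n−1), max, a composite
**weighted score** `0.5·mean + 0.3·max + 0.2·(1 − std)` and the rank by that
score (ties broken alphabetically). The composite rewards average quality,
peak quality and stability; it is an explicit package convention,
configurable via `score_weights`, and has no canonical external definition.

Weight sensitivity offers four procedures: one-way sweeps of each
coefficient over [0, 1] with the others at their base values; the simplex
grid `α + β + γ = 1` at step 0.1 (exactly 66 triples); Sobol variance
decomposition with Saltelli A/B/AB_i estimators over scrambled Sobol
samples of the unit cube (`S_i = E[f_B(f_{AB_i} − f_A)]/Var`,
`ST_i = E[(f_A − f_{AB_i})²]/(2·Var)`, zero-variance guard returning zeros);
and Kruskal–Wallis (default, distribution-free — optimizer outputs are
non-normal) with one-way ANOVA available alongside. For Sobol on the real
pipeline the per-sample objective is hybrid final fitness at a fixed seed,
folding optimizer noise into the function; an `n_rep` averaging option
exists. The all-observations-identical Kruskal–Wallis edge case returns
(H=0, p=1) since the tie-corrected statistic is undefined there. Stability
of recommendations across configurations can be quantified by the top-10
overlap of drugs ranked by selection frequency across runs.

## Synthetic data

The generator emulates the schema and marginal shape of public drug-review
tables: ratings `10·Beta(4, 2)` (right-skewed, mean ≈ 6.7 — users skew
positive), review counts negative-binomial `(r=2, p=0.1)` (mean 18, variance
180; real counts are heavily over-dispersed, spanning single digits to
thousands), and side-effect texts assembled from lexicon terms
(Poisson-distributed term count, mean 5; tier mix 40/35/25 %), so the
severity score has known ground truth. A log-normal review alternative is
provided.

Planted instances construct `k` records that strictly dominate all others on
every normalized criterion by at least `dominance_margin` (default 0.2):
near-ceiling ratings, mild-only side-effect texts, review counts pushed past
the background maximum by the margin-implied gap, with background ratings
capped and background severity floored away from the mild tier. Planting is
construction-then-verification: generate, normalize, check the margins
post-hoc, retry with boosted separation up to a bound. Strict per-criterion
dominance makes the planted subset the unique optimum for any weights with
`α, γ > 0` and `β ≥ 0`, verified by exhaustive enumeration in tests.

What passing tests on these tables shows: the optimizers navigate the
decode/penalty landscape to a provable optimum, their rankings are stable,
and every statistic in the harness computes what it claims. What it does not
show: performance on real review text (free-form vocabulary, misspellings,
negations), on criteria that are correlated rather than independently drawn,
or on tables where no dominant subset exists and the optimum is a genuine
trade-off.

## Problem sizes used in the shipped checks

The end-to-end checks use the planted 12-drug instance (`k = 3`, 220
subsets, brute-force oracle; `Np = 20, T = 200`, 20 seeds per algorithm) for
success-rate measurement, and the planted 60-drug instance (`k = 5`,
`Np = 30, T = 500`, 20 common seeds) for the ranking comparison — the
population size and iteration count of the larger benchmark match the
configuration used for the study-scale experiments. Measured at these
sizes, all three optimizers recover the small-instance optimum in ≥ 90 % of
runs and the hybrid's mean final fitness on the medium instance is at least
each baseline's.

## Known limitations

* The weighted-sum scalarization cannot express preferences over the Pareto
  front beyond linear trade-offs; no multi-objective front is computed.
* The rule-based lemmatizer handles plural inflection only; derivational
  variants ("bleed"/"bleeding") are distinct tokens unless the lexicon lists
  both.
* Sobol indices on the real pipeline inherit optimizer noise; at small
  `n_base` the estimates can leave `[0, 1]` by Monte-Carlo error.
* EAVOA's per-iteration evaluation count is stochastic (greedy two-candidate
  moves), so only the hybrid and PSO satisfy the exact eval-count doubling
  contract.
* The literal `inverse` RVSS weighting and `literal` SAM form are retained
  for comparison but are not recommended: the former prefers worse leaders
  under maximization, the latter mixes leader and particle positions
  asymmetrically.
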