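# Methods

## Scope and model

The package implements a population metaheuristic (the secretary-bird
optimization algorithm, SBOA), three enhancement strategies that
together form QHSBOA, a kernel extreme learning machine (KELM)
classifier, a hyperparameter-tuning pipeline that couples the two, a
benchmarking/statistics harness, and a synthetic tabular data generator.
Everything is seeded: each optimizer run owns a single
`numpy.random.Generator` and consumes it in a documented, fixed order,
so identical seeds give bit-identical trajectories.

## Base optimizer

Positions are initialized uniformly, `x_ij = (ub_j − lb_j)·r + lb_j`.
Iterations are counted 1..T. Hunting stages partition the run as
`iter ≤ T/3`, `T/3 < iter ≤ 2T/3`, else stage 3; this closed/open
convention covers every iteration exactly once and assigns iteration 1
to the differential search stage even for the minimal T = 3.

Numerical conventions that the printed update rules leave open:

* **Lévy flight.** `RL = 0.5 · 0.01 · u·σ / |v|^(1/η)` with η = 1.5 and
  Mantegna's σ = (Γ(1+η)·sin(πη/2) / (Γ((1+η)/2)·η·2^((η−1)/2)))^(1/η)
  ≈ 0.69657. `u, v` are standard normal — the only distribution under
  which this σ yields a Lévy-stable step; a uniform reading would make
  the step strictly positive and light-tailed.
* **Stage-2 factor.** The exhaustion move scales with `exp((iter/T)^4)`,
  which *grows* toward e as the run ends. It is implemented exactly as
  written; a decaying variant `exp(−(iter/T)^4)` would behave similarly
  early and more conservatively late, and was deliberately not
  substituted.
* **Escape branch.** One scalar U(0,1) draw per individual against
  q = 0.5 selects flee-vs-camouflage; the camouflage multiplier r4 is
  U(0,1) per dimension, the peer is drawn uniformly excluding the
  individual itself, and l ∈ {1, 2} with equal probability.
* **Selection is strict** (`<`): ties keep the incumbent, so a constant
  objective never churns the population, and the best-so-far history is
  non-increasing by construction.
* Proposals are repaired before evaluation (clipping in the base
  algorithm), so the objective is only ever evaluated inside the box;
  2N evaluations per iteration plus N at initialization.

## Enhancement strategies

* **PSO search (PSBOA).** The middle hunting stage is replaced by
  `v ← w·v + c1·α1·(x_pbest − x) + c2·α2·(x_gbest − x)`, proposal
  `x + v`, with `w = 1 − iter/T`, c1 = c2 = 2, α's U(0,1) per entry.
  Under strict greedy selection, positions coincide with personal bests,
  so the cognitive term vanishes; this is a structural consequence of
  embedding a PSO step in a greedy algorithm, not an implementation
  shortcut.
* **Dynamic boundary repair (DSBOA).** Entries above `ub_j` move to
  `(x_pbest,j + ub_j)/2`, below `lb_j` to `(x_pbest,j + lb_j)/2` —
  midpoints of two in-box points, hence always feasible. The anchor is
  the per-individual best by default; a `boundary_anchor="gbest"` switch
  anchors on the global best instead, since "best individual" admits
  both readings.
* **Quantum-rotation t mutation (QSBOA).** Once per iteration the global
  best is perturbed along four candidate directions built from
  per-dimension qubit amplitudes `(cos φ_j, sin φ_j)`, φ_j ~ U[0, 2π),
  with one shared rotation angle θ ~ U[0, 2π] applied through the planar
  rotation matrix for the second pair. Amplitudes are scaled back to
  solution space by the Euclidean norm ‖x_best‖ with an independent
  Rademacher sign per dimension per candidate, and each candidate is
  `x_best + t ⊙ direction` with per-dimension Student-t factors,
  df = iter — heavy-tailed (near-Cauchy) steps early, near-Gaussian
  late. Candidates are clipped to the box (the incumbent best must stay
  feasible) and replace the incumbent only on strict improvement, so the
  mutation can never worsen the best solution; it adds 4 evaluations per
  iteration. The amplitude-encoding of the best position is genuinely
  under-determined by its source; the mapping above satisfies
  α² + β² = 1 exactly and keeps the perturbation scale tied to the
  current solution magnitude.

Disabling all three strategies takes the identical code path as the base
algorithm, so the reduction is bit-exact under a shared seed — a
regression guard the test suite asserts.

## Test functions

The built-in suite (Sphere, Rosenbrock, Rastrigin, Ackley, Griewank,
Levy, Schwefel 2.26, at their conventional bounds) stands in for
data-file-based competition suites. `make_shifted_rotated` composes any
origin-optimum function with a seeded orthogonal rotation (sign-fixed QR
of a Gaussian matrix) and a seeded shift in the central 80% of the box,
which emulates the structure of shifted–rotated benchmark functions
while keeping the optimum known.

## KELM

Training solves `(I/C + Ω) β = T` by a symmetric positive-definite
solve (never an explicit inverse; the matrix is PSD + I/C, hence
well-conditioned for finite C). Labels are encoded ±1 and thresholded at
0 with ties going to the positive class; a single-class training set is
allowed but flagged, and predicts that class everywhere. The Gaussian
RBF is `exp(−‖·‖²/(2c²))` — the printed source form lacks the minus
sign, which cannot define a similarity kernel and is treated as an
erratum — and the width symbol c is identified with σ, the only reading
under which the [1, 20] search range is meaningful. A one-hot multiclass
path exists but is exercised only by smoke tests; the intended task is
binary.

## Tuning and evaluation protocol

The tuning objective is `1 − avgAcc` over k stratified inner folds
(k = 5 by default; the 10-fold variant is a config switch), with the
fold assignment drawn once and frozen so the optimizer sees a
deterministic objective. The outer protocol is repeated stratified
10-fold CV; the held-out fold never enters fold construction, tuning,
preprocessing statistics, or training for its own evaluation.
Imputation (column means) and min-max scaling are fit on training
portions and applied to test portions; test values outside the fitted
range are deliberately not clipped, since clipping would silently
distort distances. Constant columns map to 0. Metrics (ACC, MCC,
sensitivity, specificity, F1, recall) come from the binary confusion
matrix with the diseased class positive; any zero denominator — 
including each factor under the MCC root — defines the metric as 0. MCC
is reported dimensionless in [−1, 1]; the percentage metrics on a 0–100
scale.

The optimizer budget inside tuning defaults to population 20 and 30
iterations — a desk-scale choice, configurable; the 2-D search box
[1, 20]² is cheap and the fitness landscape has broad plateaus, so small
budgets suffice.

## Synthetic data

`generate_pidd_like` emulates the *shape* of the PIDD study data: 768
rows, 8 features, exactly 268 positives, missing values scattered
completely at random (default rate 5%; the source data's missingness
mechanism is uncharacterized, so MCAR is assumed). Features are two
unit-variance Gaussian class clouds; ⌈d/2⌉ randomly chosen features
carry a class-mean shift of `effect_size` each (default 1.3, giving a
total separation Δ = 1.3·√4 = 2.6 and a Bayes accuracy near 90% under
the 500/268 prior — a realistic level for a well-tuned classifier on
this kind of task). The generator does not copy the real dataset's
marginals, units, or feature correlations; passing tests therefore
demonstrate correct mechanics and sane statistical behaviour of the
pipeline, not clinical performance on real PIDD data.

## Comparison statistics

Benchmark runs are paired across algorithms by common random numbers
(seed = base seed + run index). Summaries report the sample mean, n−1
standard deviation, and per-problem ranks of the means (average ranks on
ties); the Friedman mean rank averages these per-problem ranks, and the
Friedman χ² statistic with its p-value is available separately. The
Wilcoxon rank-sum p-value is two-sided: for pooled sizes ≤ 12 it
enumerates the conditional permutation distribution of the midrank sum
(counting splits at least as far from the null center as observed —
equal to the classical exact two-sided p for tie-free data, and
well-defined under ties, where identical samples correctly give p = 1);
larger samples use the normal approximation with tie and continuity
corrections. One-sided variants are not offered; the comparisons here
are two-sided by design.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` uses: the five-function suite (Sphere,
Rastrigin, Ackley, Griewank, Levy) at D = 10, population 30, 200
iterations, 10 paired runs per algorithm; shift recovery on the
shifted/rotated 10-D sphere at population 30, 500 iterations, 10 seeds
with success defined as sup-norm error ≤ 1e-3; and one round of
stratified 10-fold nested CV on the default synthetic dataset with 5
inner folds and a population-8 / 12-iteration tuning budget. These sizes
were chosen as the package's desk-scale defaults; all are configurable.

## Known limitations

* **The enhanced variant is not uniformly better here.** On this
  analytic suite the base algorithm already reaches the optimum to
  floating-point dust on several functions (its best-anchored
  multiplicative moves are particularly effective when the optimum is at
  the origin), so mean-final-fitness comparisons are dominated by
  denormal-scale differences and occasional stuck runs on the
  multimodal functions. In repeated experiments the enhanced variant's
  win fraction and Friedman rank against base SBOA hover around parity
  and flip with the base seed, at both 200 and 500 iterations. Staging
  runs attribute the mid-run slowdown to the PSO phase as printed
  (c1 = c2 = 2 overshoots the global-best attractor); the quantum
  mutation is neutral-to-helpful (it cannot worsen the best) and the
  dynamic boundary repair matters only when bounds are active. The
  reproduction script reports this comparison as computed, without
  adjustment.
* The mutation's perturbation scale is ‖x_best‖, so for problems whose
  optimum is far from the origin the mutation keeps proposing
  large steps late in the run; they are wasted (elite selection) but
  cost 4 evaluations per iteration.
* Exact rank-sum enumeration is combinatorial; the pooled-size cutoff of
  12 keeps it instant, at the price of using the normal approximation
  for the 30-vs-30 comparisons typical of benchmark tables (standard
  practice).
* The synthetic generator's Gaussian clouds are ellipsoidal and
  feature-independent; real clinical tabular data have skewed marginals,
  correlated features and informative missingness, none of which are
  emulated.
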