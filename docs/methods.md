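# Methods

## Problem setting

Expression profiling of tumor cohorts (microarray mRNA panels, proteomic
spectra) produces matrices with thousands to tens of thousands of features
and only tens to a few hundred samples. Most features are irrelevant to the
clinical label (diagnosis, subtype, relapse outcome) or redundant with one
another, and classifiers fitted on the full matrix are expensive and
noisy. `pasvm` implements a two-stage pipeline for this regime:

1. **Filter** the feature set with the Fast Correlation-Based Filter
   (FCBF), an information-theoretic selector that removes both irrelevant
   and redundant features in near-linear time.
2. **Classify** with a soft-margin RBF-kernel SVM whose two
   hyperparameters — the penalty factor `C` and the kernel coefficient
   `gamma` — are tuned by a hybrid swarm optimizer ("PA"): particle swarm
   optimization (PSO) runs first and its best solution initializes the
   food sources of an artificial bee colony (ABC) search.

The hybrid's rationale: PSO converges quickly (good exploitation) but can
stall in local optima; ABC's scout phase keeps injecting global
exploration but is slow to refine. Seeding ABC with the PSO incumbent
combines the two tendencies, and greedy acceptance guarantees the hybrid
never returns anything worse than the PSO stage.

## Feature selection

**Discretization.** FCBF operates on discrete variables, so each
continuous feature is discretized against the class by recursive binary
splitting at the entropy-minimizing boundary, stopping when a split's
information gain no longer exceeds the Fayyad–Irani MDL coding cost
`(log2(N-1) + delta) / N` with
`delta = log2(3^k - 2) - [k H(S) - k1 H(S1) - k2 H(S2)]`.
A feature with no acceptable split collapses to a single bin and carries
zero information about the class. MDL discretization is the conventional
companion to symmetrical-uncertainty selectors in the Weka ecosystem; a
10-bin equal-frequency discretizer is available via
`discretizer="equal-frequency"` for comparison. Because cut placement is
order-preserving, discretization (and hence selection) is invariant to
monotone per-feature transforms, including the pipeline's z-scoring.

**Scoring.** Symmetrical uncertainty
`SU(X, Y) = 2 IG(X|Y) / (H(X) + H(Y))` with base-2 logs and empirical
probabilities; `SU = 0` by definition when both variables are constant.

**Selection.** Stage 1 keeps features with `SU(feature, class) > delta`
(`delta = 0` by default — any strictly positive association survives),
ordered by decreasing SU with ties broken by ascending column index.
Stage 2 walks the list and removes every later feature `j` predominated by
a surviving earlier feature `i`, i.e. `SU(i, j) >= SU(j, class)`, recording
the predominator. On the default synthetic regime (500 features) the
selection typically retains ~10 features, mirroring the drastic reductions
seen on real expression panels.

## Hyperparameter search

The optimizers maximize a pluggable objective over a box; for SVM tuning
the box is `(log2 C, log2 gamma) in [-8, 8]^2` (the conventional
LIBSVM-style grid range) and the objective is stratified k-fold CV
accuracy. Encoding in log2 space makes the search scale-free in the
multiplicative parameters.

**PSO.** Velocity update
`v <- w v + c1 r1 (p_i - x) + c2 r2 (p_g - x)` with position `x <- x + v`,
both clamped (velocity to ±half the box range by default). Defaults:
population 30, 100 iterations, `w = 0.729`, `c1 = c2 = 1.49445`
(constriction-equivalent standard), scalar `r1, r2` per particle per
update as in the printed update rule. A mutation operator re-randomizes
one uniformly chosen particle's position and velocity with probability 0.1
per iteration; the mutated particle keeps its personal-best memory and is
scored on the next sweep, so the evaluation count is exactly
`n_particles x (n_iterations + 1)`. The operator itself is this package's
design choice — the idea of PSO-with-mutation is standard, but no single
canonical form exists.

**ABC.** Population 30 food sources, 100 iterations, scout limit 50.
Employed phase: one neighborhood proposal per source,
`x_i' = x_i + r (x_i - x_j)` with `r ~ U(-1, 1)` applied to one uniformly
chosen dimension (the canonical single-dimension move; the all-dimension
variant degrades fine refinement), greedily accepted. Onlooker phase: N
further proposals allocated by fitness-proportional roulette
`P_i = fit_i / sum(fit)`; non-positive fitness vectors are shifted by
`-min + 1e-12` before normalizing (defensive — accuracy fitness is in
[0, 1]), and an all-equal vector yields uniform probabilities. Scout
phase: a source unimproved for more than `limit` trials is resampled
uniformly. The best-so-far solution is tracked across replacements.

**PA hybrid.** PSO runs to completion; ABC is then initialized with food
source 0 equal to the PSO best, sources `1..ceil(N/2)` equal to the best
perturbed by up to ±10% of each dimension's range, and the remainder
sampled uniformly — balancing exploitation of the seed against ABC's
exploration. Both stages run their full budgets by default (100 + 100
iterations). `run_pa(..., equal_budget=True)` instead halves the PSO stage
and gives ABC only the evaluations that remain of a PSO-only budget, for
evaluation-fair comparisons.

**Benchmarking choice.** The head-to-head Rastrigin benchmark in the
acceptance suite equalizes budgets by scaling the single-method arms *up*
to the hybrid's natural total (~9,090 evaluations: PSO-only 302
iterations, ABC-only 151) rather than shrinking the hybrid. At that budget
all arms converge to the optimum within double precision on 2-D Rastrigin
and the comparison tests the intended property (the hybrid is never
worse). Shrinking the hybrid to a 3,030-evaluation budget instead turns
the comparison into a race of numerical polish far below 1e-6 — all arms
in the global basin, differences physically meaningless — which the
package does not treat as a meaningful ranking.

**Determinism.** Every stochastic component draws from
`numpy.random.default_rng(seed)`; identical configs and seeds give
bit-identical traces. Non-finite objective values abort with the offending
position named.

## Fitness and the end-to-end fit

The tuning objective is mean stratified k-fold CV accuracy (k = 10). Folds
are fixed by a fold seed for the whole optimization run so all candidate
`(C, gamma)` pairs are scored on identical splits — the objective is
deterministic and candidate comparisons are paired. Positions rounded to
1e-6 in log2 space are memoized; this changes evaluation cost only, never
results. If a class has fewer than k members, k is clamped to the smallest
class size with a warning. A single-class training split (impossible under
stratification, handled defensively) is scored as the majority-class rate
on its test split.

`fit_pa_svm` chains: z-score standardization (sample std, n−1 denominator;
constant features map to zero with recorded std 1) → FCBF → hybrid search
→ final SVM trained on all samples at the tuned parameters. The model
bundle stores the selection indices, standardization parameters, tuned
`(C, gamma)` and fitted SVM, and accepts raw matrices with the original
feature count at prediction time. Multiclass labels use the LIBSVM-style
one-vs-one decomposition of the delegated solver.

Following the original experimental protocol, FCBF runs once on the full
dataset *before* cross-validation. This leaks label information into the
selection, so the reported CV accuracy is an inner, optimistically biased
estimate; `nested_cv_accuracy` (CLI `--nested`) re-runs standardization
and selection inside each training fold at fixed `(C, gamma)` for an
honest generalization estimate. Which of the two a published
accuracy-comparison table reports is usually ambiguous; this package
reports the inner-CV fitness as the headline and the nested estimate on
request.

`compare_methods` reproduces the repeated-runs protocol: R runs (seeds
`base_seed..base_seed+R−1`) of each arm — default-parameter SVM, PSO-only,
ABC-only, hybrid — on the same FCBF-reduced matrix, reporting best-of-R
(the headline convention of the protocol) alongside the median, since
best-of-R overstates performance.

## Synthetic data

Real expression panels from public repositories are not redistributable
desk-scale inputs, so the generator emulates their statistical shape: 60
samples split evenly between 2 classes, 10 informative features
(class-conditional normals with adjacent class means `effect_size = 2`
within-class standard deviations apart), 10 redundant features (exact
copies of the informative ones at the default `redundancy_noise = 0`), and
480 irrelevant standard-normal features, columns randomly permuted with
provenance kept in the feature names. The defaults give a strongly
separable problem analogous to the datasets on which tuned SVMs reach
100% CV accuracy; lowering `effect_size` or raising `redundancy_noise`
produces harder regimes.

What the generator does *not* emulate: heavy-tailed and batch-structured
noise, feature-feature correlation beyond exact duplication, class
imbalance, or measurement missingness. Passing tests on this generator
therefore demonstrate correctness of the algorithms under their stated
model, not expected accuracy on clinical data.

Two properties of the default regime are worth knowing when reading test
output. First, an exact redundant copy is indistinguishable from its
source, so which of the pair survives selection (and hence whether the
survivor's name says `inf_` or `red_`) is decided by the arbitrary
tie-break after column permutation. Second, MDL discretization has a small
but nonzero false-positive rate (~0.3% per feature at n = 60), so among
480 irrelevant features one or two typically leak into the selection; this
is inherent to the criterion, not a defect of the search, and the planted
structure check in the acceptance suite measures exactly this leakage.

## Problem sizes and tolerances

Analytic benchmarks run at the standard budget (population 30, 100
iterations); the end-to-end fit uses the same budget on the 60 × 500
synthetic dataset; the comparison harness uses 10 × 15 per arm for its 4
arms × 10 runs. Optimum recovery is asserted to 1e-3 on the sphere;
probability normalization to 1e-12; SU against the brute-force oracle to
1e-12; Monte-Carlo generator checks at n = 10,000 with tolerance a few
standard errors wide.

## Known limitations

- Best-of-R reporting inflates accuracy; use the recorded medians for a
  fair view.
- Whole-dataset feature selection before CV inflates the headline accuracy
  (see nested CV above).
- The FCBF `delta` threshold cannot remove MDL false positives without
  also removing weak true signals; on real panels some spurious features
  will survive selection at `delta = 0`.
- The optimizers are serial; no parallel or asynchronous swarm variants.
- No missing-value imputation and no normalization beyond z-scoring:
  inputs with missing entries are rejected.
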