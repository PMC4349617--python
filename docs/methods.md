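# Methods

## Model and procedure

`metasurv` treats prognostic-marker discovery as a constrained subset
search. A candidate solution is a transcript set *G* of fixed size *r*
together with RBF-SVM hyperparameters `γ = 2^(g−7)`, `C = 2^(c−7)` for
4-bit codes `g, c ∈ {0..15}`. Its score is

    f(G) = w · Acc(G) + (1 − w) · max(Asurv(G), 0)

* **Acc** — leave-one-out cross-validation accuracy of the SVM restricted
  to *G*. LOOCV is exact: libsvm's built-in n-fold cross-validation with
  n folds is deterministic leave-one-out; we verified it reproduces an
  explicit per-fold fit bit-for-bit across randomized settings, and fall
  back to the per-fold path whenever a class has fewer than two members
  (one-class training folds then predict their majority class and log a
  warning).
* **Asurv** — the disease-free survival area of the *predicted* groups:
  one Kaplan-Meier curve per predicted group (predicted non-metastasis
  first), signed area between them integrated exactly over `[0, t_max]`
  and normalized by `t_max`. Predicted groups, not true labels, because
  the statistic must score candidate classifiers; the real-class area is
  a diagnostic reference. The signed value is kept (a negative sign flags
  an inverted grouping) and clamped to 0 only inside `f`.

`t_max` defaults to the largest observed DFS time in the training cohort
and is configurable. KM estimation processes events before censorings at
tied times (the standard product-limit convention); censor-only times
create no drop. The estimator is a direct vectorized product-limit —
cheap enough for the GA's inner loop, where it runs once per fitness
evaluation — and is cross-checked against lifelines in the test suite.

## The optimizer

The inheritable bi-objective combinatorial GA solves C(n, r) for
r = r_start..r_end in one run. Defaults (full budget): r 10..30,
population 60, crossover probability 0.8, mutation probability 0.05, 60
generations per stage, 30 independent runs, w = 0.8.

* **Selection** — size-2 tournaments, two draws with replacement per
  tournament, higher `f` wins, ties split at random.
* **Orthogonal-array crossover** — parents with equal *r* differ at an
  even number of mask positions, half carried by each parent. Each
  parent1-one is paired with a parent2-one (position order) and the pairs
  are grouped into at most 7 balanced factor blocks (differing γ/C code
  genes are additional factors). Balanced blocks make every block
  exchange weight-preserving, so the orthogonal design is evaluated
  without any stochastic repair and the main-effect analysis is
  deterministic; a random-flip repair remains as a safety net. The
  two-level array L_M(2^k), M = 2^⌈log₂(k+1)⌉, uses Walsh columns 1..k;
  all M rows plus the main-effect composite are evaluated and the two
  best distinct candidates become the children. On additive objectives
  the composite provably reaches the block-wise optimum, which the test
  suite checks by exhaustive enumeration.
* **Mutation** — swaps one selected with one unselected transcript
  (preserving r); each code gene is re-randomized with probability 0.1
  (the operator only needs occasional hyperparameter exploration; the
  codes are also recombined by crossover). The stage-best individual is
  exempt.
* **Elitism / inheritance** — the stage best survives every generation;
  at stage end every individual flips one random 0-bit to 1 and the
  search continues at r+1. Fitness evaluations are memoized per run and
  counted; the budget bound
  `stages · Gmax · (N_pop + p_c·N_pop·(M+1)/2)` is asserted in tests.
* **Aggregation** — per-run bests are tallied into appearance counts.
  S_a is the highest-fitness solution; S_b maximizes the appearance
  score `0.5·f/max_f + 0.5·mean_g count(g)/R`, a concrete realization of
  "fitness plus mean selection frequency" (the literature formula behind
  it is not fully specified anywhere we could follow).

## Refinement and evaluation

* **Appearance shortlist** — top-k transcripts by count; ties break by
  the higher mean fitness of the solutions containing the transcript,
  then lexicographic id.
* **SBS** — from the shortlist down to one transcript; every candidate
  removal is scored with a full 16×16 hyperparameter grid search
  (maximum `f`; grid ties prefer the smallest C code, then the smallest
  γ code — smoother models, deterministically). Removal ties drop the
  transcript with the larger univariate p. Both the argmax-f and the
  argmax-Asurv sets along the trajectory are reported, since a panel is
  often chosen for its survival separation.
* **Ensemble** — 30 RBF-SVMs, each on 5 transcripts drawn uniformly
  without replacement from the panel, each grid-tuned on the training
  cohort with w = 1 (members are plain classifiers; the survival term
  belongs to selection, not to member tuning); majority vote with 15-15
  ties resolved toward the metastasis class (favoring sensitivity).
* **SVR** — epsilon-insensitive support-vector regression of DFS months,
  ε fixed at 0.1 months, γ/C grid-searched by leave-one-out CV MAE.
  Selecting the grid cell on the training fit would always crown the pure
  interpolator (train MAE → 0, R → 1), so cross-validated error picks the
  model and the reported MAE and Pearson R are then the training-set fit
  of that model.
* **Univariate table** — per-transcript pooled two-sample t-test p,
  single-transcript grid-best LOOCV accuracy, and the survival area of
  that classifier's predictions; three rank columns (1 = best), ties
  broken by transcript id. The univariate t-test is Student's pooled
  two-sample test, two-sided; Welch's variant is exposed as an option.
* **EMT filter** — keeps transcripts annotated with one of the five EMT
  regulator categories (growth factor, ligand-dependent nuclear receptor,
  transcription regulator, cytokine, kinase; unannotated transcripts
  count as `other`), ranks by t-test p ascending and truncates to k
  (k = 474 by default — a count, not a p threshold, for exact
  reproducibility).

## Synthetic cohorts

The generator emulates the cohort structure the method assumes, not any
particular dataset: 78 samples (37 non-distant / 41 distant), 474
candidate transcripts, 10 informative ones shifted by 1.5 noise-SDs in
the distant class, unit noise SD. Distant-class DFS is exponential with
mean 14 months truncated at the 120-month horizon, all events observed;
non-distant DFS is exponential with latent mean 90 months censored
uniformly in 60–120 months — reproducing the heavy censoring asymmetry
of surgical follow-up. A paired generator emits an independent 26-sample
test cohort (6:20 balance) from the same process.

Class membership drives expression and survival **independently**; there
is no expression→survival link beyond the class. Two consequences matter
for interpreting the tests. First, this is exactly the dependence the
fitness exploits, so planted-marker recovery is a fair end-to-end check.
Second, within-class samples are exchangeable, so the survival term can
add no information beyond the labels: the expected held-out advantage of
w = 0.8 over w = 1.0 is zero here, and the corresponding check is a
*no-harm* check (median advantage non-negative, ties counting). A
positive advantage on real cohorts rests on survival carrying
class-related signal that accuracy alone misses — a structure this
generator deliberately does not fabricate; passing tests therefore do
not demonstrate that real-data benefit.

The generator also emits regulator-category annotation for the filter
stage (planted transcripts always within EMT categories, 80% of the rest
EMT, 20% `other`).

## Problem sizes used in tests and the acceptance script

Honest wrapper selection is expensive (every fitness call is a full
LOOCV), so the shipped experiments scale the search, not the method:

* shortlist recovery: 60 samples × 120 transcripts (filter keeps 100),
  5 planted, stages r = 4..8, budget R = 5 / Gmax = 15 / N_pop = 20,
  5 master seeds;
* exhaustive-oracle recovery: 70 samples × 30 transcripts, 3 planted at
  effect 1.8 (moderate on purpose — a very strong effect lets two of the
  three planted transcripts classify perfectly, creating ties and no
  unique optimum), single stage r = 3, population 40 for 80 generations,
  20 seeded runs; the exhaustive C(30,3) scan verifies the planted triple
  is the unique optimum before the GA is scored against it;
* the acceptance script: full-size 78×474 cohort pair, GA at r = 5..10,
  N_pop = 20, Gmax = 10, R = 5, SBS from a 12-transcript shortlist.

## Numerical choices and degenerate inputs

Grid ties: smallest C code, then smallest γ code. Ensemble vote ties: the
metastasis class. Empty predicted group: Asurv = 0 with the empty size
flagged. Constant transcript: univariate p = 1, LOOCV predicts fold
majorities. Constant SVR target: an error. All randomness flows from
numpy Generators; per-run GA seeds are `master + run_index (mod 2³¹)`,
so a fixed master seed yields bit-identical run ensembles, which the
tests assert.

## Known limitations

Expression correlation structure, batch effects, and probe-level noise
are not modeled. The appearance-score formula for S_b is one reasonable
realization, not a canonical one. SBS is greedy: it is not guaranteed to
reach the best subset of a given size, only never to be worse than the
start set along its own path. The weight-sweep experiment at full GA
budget is computationally heavy; the default CLI budget is reduced and
configurable.
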