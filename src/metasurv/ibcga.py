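"""Inheritable bi-objective combinatorial GA for transcript-subset search.

The optimizer solves the feature-subset problems C(n, r) for r from
``r_start`` to ``r_end`` in a single run: each stage evolves a population of
binary masks with exactly r ones (plus two 4-bit genes encoding the RBF-SVM
gamma and C) for ``Gmax`` generations, records the stage best S_r, then
*inherits* the whole population into the next stage by flipping one random
0-bit to 1 in every individual.  Recombination is orthogonal-array
crossover: the positions where two parents differ are grouped into at most
seven factor blocks, a two-level orthogonal array prescribes a small set of
block exchanges, and a composite offspring is assembled from the better
level of each factor by main-effect analysis.

R independent runs are aggregated into per-transcript appearance counts;
the most accurate solution (S_a, highest fitness) and the most robust one
(S_b, highest appearance score) are both reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from metasurv.classify import FitnessBreakdown, SVMParams, _fitness_from_predictions, \
    _loocv_precomputed, _pairwise_sq_dists, decode_log2_param
from metasurv.cohort import Cohort, SelectionResult
from metasurv.survival import default_t_max

logger = logging.getLogger(__name__)

#: cap on the number of OA factors (an L8 array at most)
MAX_OA_FACTORS = 7


@dataclass
class Chromosome:
    """A binary transcript mask with exactly r ones plus two 4-bit codes."""

    mask: np.ndarray
    gamma_code: int
    c_code: int
    fitness: FitnessBreakdown | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        SVMParams(self.gamma_code, self.c_code)  # validates code range

    @property
    def r(self) -> int:
        return int(self.mask.sum())

    def key(self) -> tuple:
        return (self.mask.tobytes(), self.gamma_code, self.c_code)

    def copy(self) -> "Chromosome":
        return Chromosome(self.mask.copy(), self.gamma_code, self.c_code, self.fitness)


@dataclass(frozen=True)
class GAConfig:
    """IBCGA settings; defaults are the standard full-budget configuration."""

    r_start: int = 10
    r_end: int = 30
    pop_size: int = 60
    p_c: float = 0.8
    p_m: float = 0.05
    gmax: int = 60
    runs: int = 30
    w: float = 0.8
    seed: int = 0
    t_max: float | None = None

    def validate(self, n_transcripts: int) -> None:
        if not 1 <= self.r_start <= self.r_end <= n_transcripts:
            raise ValueError(
                f"need 1 <= r_start <= r_end <= n ({self.r_start}, {self.r_end}, "
                f"{n_transcripts})"
            )
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        for name, p in (("p_c", self.p_c), ("p_m", self.p_m), ("w", self.w)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.gmax < 1 or self.runs < 1:
            raise ValueError("gmax and runs must be >= 1")


@dataclass
class IbcgaRunResult:
    """Stage solutions S_r and the best of one IBCGA run."""

    stage_solutions: dict[int, SelectionResult]
    best: SelectionResult
    n_evaluations: int


@dataclass
class RunEnsemble:
    """The R independent runs' best solutions and appearance statistics."""

    solutions: list[SelectionResult]
    appearance_counts: dict[str, int]
    s_a: SelectionResult
    s_b: SelectionResult
    runs: int

    def appearance_score(self, solution: SelectionResult) -> float:
        """0.5 * f/max_f + 0.5 * mean appearance fraction of the members."""
        max_f = max(s.fitness.f for s in self.solutions)
        fit_part = solution.fitness.f / max_f if max_f > 0 else 0.0
        mean_count = float(
            np.mean([self.appearance_counts.get(t, 0) for t in solution.transcript_ids])
        )
        return 0.5 * fit_part + 0.5 * mean_count / self.runs


class FitnessEvaluator:
    """Memoized fitness oracle for chromosomes over one cohort.

    Counts true evaluations (cache misses) for budget accounting.  The
    squared-distance computation is done per mask; the LOOCV uses the
    precomputed-kernel path shared with the classification module.
    """

    def __init__(self, cohort: Cohort, w: float, t_max: float | None = None):
        cohort.require_both_classes()
        self.cohort = cohort
        self.w = float(w)
        self.t_max = default_t_max(cohort) if t_max is None else float(t_max)
        self.n_evaluations = 0
        self._memo: dict[tuple, FitnessBreakdown] = {}

    def __call__(self, chrom: Chromosome) -> FitnessBreakdown:
        key = chrom.key()
        fb = self._memo.get(key)
        if fb is None:
            cols = np.nonzero(chrom.mask)[0]
            if cols.size == 0:
                raise ValueError("cannot evaluate an empty transcript mask")
            D = _pairwise_sq_dists(self.cohort.expression[:, cols])
            K = np.exp(-decode_log2_param(chrom.gamma_code) * D)
            preds = _loocv_precomputed(
                K, self.cohort.class_labels, decode_log2_param(chrom.c_code)
            )
            fb = _fitness_from_predictions(self.cohort, preds, self.w, self.t_max)
            self._memo[key] = fb
            self.n_evaluations += 1
        chrom.fitness = fb
        return fb


# ---------------------------------------------------------------------------
# GA operators
# ---------------------------------------------------------------------------

def init_population(
    n: int, r: int, pop_size: int, rng: np.random.Generator
) -> list[Chromosome]:
    """Uniform random r-subsets with uniform 4-bit hyperparameter codes."""
    if r > n:
        raise ValueError(f"r={r} exceeds n={n}")
    population = []
    for _ in range(pop_size):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=r, replace=False)] = True
        population.append(
            Chromosome(
                mask=mask,
                gamma_code=int(rng.integers(16)),
                c_code=int(rng.integers(16)),
            )
        )
    return population


def tournament_select(
    population: list[Chromosome], rng: np.random.Generator
) -> list[Chromosome]:
    """Size-2 tournaments (draws with replacement); higher f wins, ties random.

    Returns a pool of ``len(population)`` winners (copies).
    """
    if any(c.fitness is None for c in population):
        raise ValueError("population must be fully evaluated before selection")
    n = len(population)
    pool = []
    for _ in range(n):
        i, j = rng.integers(n), rng.integers(n)
        fi, fj = population[i].fitness.f, population[j].fitness.f
        if fi > fj:
            winner = population[i]
        elif fj > fi:
            winner = population[j]
        else:
            winner = population[i if rng.integers(2) == 0 else j]
        pool.append(winner.copy())
    return pool


def _repair_mask(
    mask: np.ndarray, r: int, diff_positions: np.ndarray, rng: np.random.Generator
) -> None:
    """Restore sum(mask) == r by random flips among the differing positions."""
    excess = int(mask.sum()) - r
    if excess > 0:
        ones = diff_positions[mask[diff_positions]]
        mask[rng.choice(ones, size=excess, replace=False)] = False
    elif excess < 0:
        zeros = diff_positions[~mask[diff_positions]]
        mask[rng.choice(zeros, size=-excess, replace=False)] = True


def oa_crossover(
    parent1: Chromosome,
    parent2: Chromosome,
    fitness_fn,
    rng: np.random.Generator,
) -> tuple[Chromosome, Chromosome, int]:
    """Orthogonal-array crossover of two chromosomes.

    Because both parents carry exactly r ones, the positions where they
    differ split evenly into parent1-ones and parent2-ones.  Each
    parent1-one is paired (in position order) with a parent2-one, and the
    pairs are grouped into at most :data:`MAX_OA_FACTORS` factor blocks —
    balanced blocks, so every block exchange preserves the mask weight and
    no stochastic repair perturbs the design.  A two-level orthogonal
    array L_M(2^k) with M = 2^ceil(log2(k+1)) rows (differing code genes
    are factors too) prescribes M candidate offspring, all evaluated; a
    composite offspring takes the better level of each factor by
    main-effect analysis.  The two highest-fitness distinct candidates
    become the children.  Returns (child1, child2, n_evals).
    """
    if parent1.mask.size != parent2.mask.size or parent1.r != parent2.r:
        raise ValueError("parents must share n and r")
    r = parent1.r
    diff = np.nonzero(parent1.mask != parent2.mask)[0]
    code_factors = [
        name
        for name, a, b in (
            ("gamma", parent1.gamma_code, parent2.gamma_code),
            ("c", parent1.c_code, parent2.c_code),
        )
        if a != b
    ]
    if diff.size == 0 and not code_factors:
        return parent1.copy(), parent2.copy(), 0

    factors: list[tuple[str, np.ndarray | None]] = []
    if diff.size:
        ones1 = diff[parent1.mask[diff]]
        ones2 = diff[parent2.mask[diff]]
        # equal-r parents guarantee |ones1| == |ones2|
        pairs = np.column_stack((ones1, ones2))
        n_mask_factors = max(1, min(len(pairs), MAX_OA_FACTORS - len(code_factors)))
        for block in np.array_split(pairs, n_mask_factors):
            if block.size:
                factors.append(("mask", block.ravel()))
    for name in code_factors:
        factors.append((name, None))

    k = len(factors)
    M = 1 << int(np.ceil(np.log2(k + 1)))
    # Walsh columns 1..k of the M-row two-level orthogonal array
    levels = np.empty((M, k), dtype=int)
    for j in range(k):
        col = j + 1
        levels[:, j] = [bin(i & col).count("1") % 2 for i in range(M)]

    def build(level_row: np.ndarray) -> Chromosome:
        mask = parent1.mask.copy()
        gamma_code, c_code = parent1.gamma_code, parent1.c_code
        for (kind, block), lev in zip(factors, level_row):
            if lev == 0:
                continue
            if kind == "mask":
                mask[block] = parent2.mask[block]
            elif kind == "gamma":
                gamma_code = parent2.gamma_code
            else:
                c_code = parent2.c_code
        if diff.size:
            _repair_mask(mask, r, diff, rng)
        return Chromosome(mask=mask, gamma_code=gamma_code, c_code=c_code)

    n_evals = 0
    candidates = []
    for i in range(M):
        cand = build(levels[i])
        cand.fitness = fitness_fn(cand)
        n_evals += 1
        candidates.append(cand)

    fvals = np.array([c.fitness.f for c in candidates])
    composite_levels = np.empty(k, dtype=int)
    for j in range(k):
        mean0 = fvals[levels[:, j] == 0].mean()
        mean1 = fvals[levels[:, j] == 1].mean()
        composite_levels[j] = 1 if mean1 > mean0 else 0
    composite = build(composite_levels)
    composite.fitness = fitness_fn(composite)
    n_evals += 1
    candidates.append(composite)

    order = sorted(
        range(len(candidates)), key=lambda i: candidates[i].fitness.f, reverse=True
    )
    children: list[Chromosome] = []
    seen = set()
    for i in order:
        key = candidates[i].key()
        if key in seen:
            continue
        seen.add(key)
        children.append(candidates[i])
        if len(children) == 2:
            break
    if len(children) == 1:
        children.append(children[0].copy())
    return children[0], children[1], n_evals


#: probability that each 4-bit code gene is re-randomized inside `mutate`
CODE_MUTATION_PROB = 0.1


def mutate(chrom: Chromosome, rng: np.random.Generator) -> Chromosome:
    """In-place swap mutation preserving the number of selected transcripts.

    One randomly chosen selected gene trades places with one unselected
    gene (no-op when the mask is all ones); each hyperparameter code is
    independently re-randomized with probability
    :data:`CODE_MUTATION_PROB`.  The caller is responsible for exempting
    the stage-best individual (elitism).
    """
    ones = np.nonzero(chrom.mask)[0]
    zeros = np.nonzero(~chrom.mask)[0]
    if zeros.size and ones.size:
        chrom.mask[rng.choice(ones)] = False
        chrom.mask[rng.choice(zeros)] = True
    if rng.random() < CODE_MUTATION_PROB:
        chrom.gamma_code = int(rng.integers(16))
    if rng.random() < CODE_MUTATION_PROB:
        chrom.c_code = int(rng.integers(16))
    chrom.fitness = None
    return chrom


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def _to_result(
    chrom: Chromosome, cohort: Cohort, provenance: str
) -> SelectionResult:
    ids = [cohort.transcript_ids[i] for i in np.nonzero(chrom.mask)[0]]
    return SelectionResult(
        transcript_ids=ids,
        fitness=chrom.fitness,
        gamma_code=chrom.gamma_code,
        c_code=chrom.c_code,
        provenance=provenance,
    )


def ibcga_run(
    cohort: Cohort,
    config: GAConfig,
    rng: np.random.Generator,
    evaluator: FitnessEvaluator | None = None,
) -> IbcgaRunResult:
    """One IBCGA run: stages r_start..r_end, each evolved for Gmax generations.

    Per stage: tournament selection, OA crossover on p_c*N_pop parents,
    swap mutation on p_m*N_pop individuals (never the stage best), elitism;
    the stage best is recorded as S_r.  Inheritance then flips one random
    0-bit to 1 in every individual and moves to stage r+1.
    """
    n = cohort.n_transcripts
    config.validate(n)
    if evaluator is None:
        evaluator = FitnessEvaluator(cohort, w=config.w, t_max=config.t_max)

    pop = init_population(n, config.r_start, config.pop_size, rng)
    stage_solutions: dict[int, SelectionResult] = {}
    best_overall: Chromosome | None = None

    for r in range(config.r_start, config.r_end + 1):
        for chrom in pop:
            evaluator(chrom)
        stage_best = max(pop, key=lambda c: c.fitness.f).copy()

        for gen in range(config.gmax):
            pool = tournament_select(pop, rng)
            n_parents = int(round(config.p_c * config.pop_size))
            n_parents -= n_parents % 2
            if n_parents >= 2:
                parent_idx = rng.choice(len(pool), size=n_parents, replace=False)
                for a, b in zip(parent_idx[0::2], parent_idx[1::2]):
                    c1, c2, _ = oa_crossover(pool[a], pool[b], evaluator, rng)
                    pool[a], pool[b] = c1, c2
            # mutation: p_m * N_pop random individuals, never the pool best
            n_mut = int(round(config.p_m * config.pop_size))
            if n_mut and len(pool) > 1:
                pool_best = max(range(len(pool)), key=lambda i: pool[i].fitness.f)
                eligible = [i for i in range(len(pool)) if i != pool_best]
                for i in rng.choice(eligible, size=min(n_mut, len(eligible)), replace=False):
                    mutate(pool[i], rng)
            for chrom in pool:
                evaluator(chrom)
            # elitism: the stage best survives every generation
            if stage_best.key() not in {c.key() for c in pool}:
                worst = min(range(len(pool)), key=lambda i: pool[i].fitness.f)
                pool[worst] = stage_best.copy()
            pop = pool
            gen_best = max(pop, key=lambda c: c.fitness.f)
            if gen_best.fitness.f > stage_best.fitness.f:
                stage_best = gen_best.copy()

        logger.info(
            "stage r=%d best f=%.4f (acc=%.4f, asurv=%.4f)",
            r, stage_best.fitness.f, stage_best.fitness.acc, stage_best.fitness.asurv,
        )
        stage_solutions[r] = _to_result(stage_best, cohort, provenance=f"ibcga stage r={r}")
        if best_overall is None or stage_best.fitness.f > best_overall.fitness.f:
            best_overall = stage_best.copy()

        if r < config.r_end:
            # inheritance: every individual (elite included) flips one 0 -> 1
            for chrom in pop:
                zeros = np.nonzero(~chrom.mask)[0]
                chrom.mask[rng.choice(zeros)] = True
                chrom.fitness = None

    best = _to_result(best_overall, cohort, provenance="ibcga run best")
    return IbcgaRunResult(
        stage_solutions=stage_solutions,
        best=best,
        n_evaluations=evaluator.n_evaluations,
    )


def evaluation_budget(config: GAConfig, n_stages: int | None = None) -> int:
    """Upper bound on fitness evaluations per run (budget invariant)."""
    if n_stages is None:
        n_stages = config.r_end - config.r_start + 1
    M = 8  # largest OA (L8) -> at most M + 1 evaluations per crossover pair
    per_gen = config.pop_size + config.p_c * config.pop_size * (M + 1) / 2
    return int(np.ceil(n_stages * config.gmax * per_gen + config.pop_size))


def multi_run(cohort: Cohort, config: GAConfig) -> RunEnsemble:
    """R independent IBCGA runs aggregated into appearance statistics.

    Per-run seeds are ``(seed + run_index) mod 2^31``.  ``s_a`` is the
    highest-fitness run best; ``s_b`` maximizes the appearance score
    (0.5 * normalized fitness + 0.5 * mean member appearance fraction).
    """
    config.validate(cohort.n_transcripts)
    solutions: list[SelectionResult] = []
    for run in range(config.runs):
        seed = (config.seed + run) % (2**31)
        rng = np.random.default_rng(seed)
        result = ibcga_run(cohort, config, rng)
        best = replace(result.best, provenance=f"run {run} seed {seed}")
        solutions.append(best)

    counts: dict[str, int] = {}
    for sol in solutions:
        for t in sol.transcript_ids:
            counts[t] = counts.get(t, 0) + 1

    s_a = max(solutions, key=lambda s: s.fitness.f)
    ensemble = RunEnsemble(
        solutions=solutions,
        appearance_counts=counts,
        s_a=s_a,
        s_b=s_a,  # provisional; fixed below
        runs=config.runs,
    )
    ensemble.s_b = max(solutions, key=ensemble.appearance_score)
    return ensemble
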