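"""GA operators and the IBCGA run: invariants, oracles, determinism."""

import numpy as np
import pytest

from metasurv.classify import FitnessBreakdown
from metasurv.ibcga import (
    Chromosome,
    FitnessEvaluator,
    GAConfig,
    evaluation_budget,
    ibcga_run,
    init_population,
    multi_run,
    mutate,
    oa_crossover,
    tournament_select,
)

from conftest import make_cohort


def chrom(mask, g=7, c=7, f=None):
    ch = Chromosome(mask=np.asarray(mask, dtype=bool), gamma_code=g, c_code=c)
    if f is not None:
        ch.fitness = FitnessBreakdown.compute(f, 0.0, 1.0)
    return ch


def additive_fitness(weights):
    """Toy fitness: normalized weighted sum of selected positions (w=1)."""
    total = 2.0 * (np.abs(weights).sum() or 1.0)

    def fn(ch):
        # strictly inside [0, 1]: no clipping, so the map stays additive
        acc = float(weights[ch.mask].sum() / total + 0.5)
        return FitnessBreakdown.compute(acc, 0.0, 1.0)

    return fn


# ---------------------------------------------------------------------------
# init & selection
# ---------------------------------------------------------------------------

def test_init_full_mask_when_r_equals_n():
    pop = init_population(5, 5, 4, np.random.default_rng(0))
    assert all(p.mask.all() for p in pop)


def test_init_exact_r_ones():
    pop = init_population(20, 5, 60, np.random.default_rng(1))
    assert all(p.r == 5 for p in pop)
    assert all(0 <= p.gamma_code <= 15 and 0 <= p.c_code <= 15 for p in pop)


def test_init_marginal_selection_frequency():
    rng = np.random.default_rng(2)
    n, r, trials = 20, 5, 10_000
    counts = np.zeros(n)
    for _ in range(trials):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=r, replace=False)] = True
        counts += mask
    # binomial(trials, r/n): mean r/n, sigma = sqrt(p(1-p)/trials)
    p = r / n
    sigma = np.sqrt(p * (1 - p) / trials)
    assert np.all(np.abs(counts / trials - p) < 3.5 * sigma + 1e-9)


def test_tournament_requires_evaluation():
    pop = [chrom([1, 0]), chrom([0, 1])]
    with pytest.raises(ValueError):
        tournament_select(pop, np.random.default_rng(0))


def test_tournament_best_inclusion_matches_closed_form():
    # P(best in pool) = 1 - ((N-1)/N)^(2N) for N draws-with-replacement pairs
    N = 60
    rng = np.random.default_rng(3)
    pop = [chrom(np.eye(N, dtype=bool)[i], f=0.5) for i in range(N)]
    pop[17].fitness = FitnessBreakdown.compute(0.9, 0.0, 1.0)
    hits = 0
    trials = 2000
    for _ in range(trials):
        pool = tournament_select(pop, rng)
        hits += any(p.fitness.f == pytest.approx(0.9) for p in pool)
    expected = 1 - ((N - 1) / N) ** (2 * N)
    se = np.sqrt(expected * (1 - expected) / trials)
    assert abs(hits / trials - expected) < 4 * se


def test_tournament_two_individual_expectation():
    # enumeration of the 4 equally likely draws gives 3/4 for the better
    rng = np.random.default_rng(4)
    pop = [chrom([1, 0], f=1.0), chrom([0, 1], f=0.0)]
    frac = np.mean(
        [
            np.mean([p.fitness.f for p in tournament_select(pop, rng)])
            for _ in range(3000)
        ]
    )
    assert abs(frac - 0.75) < 0.02


def test_tournament_uniform_when_all_equal():
    rng = np.random.default_rng(5)
    N = 4
    pop = [chrom(np.eye(N, dtype=bool)[i], f=0.5) for i in range(N)]
    counts = np.zeros(N)
    for _ in range(4000):
        for p in tournament_select(pop, rng):
            counts[np.argmax(p.mask)] += 1
    frac = counts / counts.sum()
    assert np.all(np.abs(frac - 0.25) < 0.02)


# ---------------------------------------------------------------------------
# OA crossover
# ---------------------------------------------------------------------------

def test_oa_identical_parents_no_evaluations():
    p1 = chrom([1, 1, 0, 0], f=0.6)
    p2 = chrom([1, 1, 0, 0], f=0.6)
    c1, c2, n_evals = oa_crossover(p1, p2, None, np.random.default_rng(0))
    assert n_evals == 0
    np.testing.assert_array_equal(c1.mask, p1.mask)
    np.testing.assert_array_equal(c2.mask, p2.mask)


def test_oa_composite_matches_exhaustive_three_factors():
    # parents differ at 6 positions = 3 balanced pair-factors; additive
    # fitness makes the factor-wise optimum the global optimum over all
    # 2^3 block combinations, which the main-effect composite must find
    rng = np.random.default_rng(6)
    for trial in range(25):
        n = 12
        weights = rng.normal(size=n)
        base = np.zeros(n, dtype=bool)
        base[[0, 1, 2]] = True  # shared ones
        p1 = base.copy()
        p2 = base.copy()
        p1[[3, 5, 7]] = True
        p2[[4, 6, 8]] = True
        fn = additive_fitness(weights)
        parent1, parent2 = chrom(p1), chrom(p2)
        parent1.fitness = fn(parent1)
        parent2.fitness = fn(parent2)
        c1, _, n_evals = oa_crossover(parent1, parent2, fn, rng)
        # exhaustive: each pair (p1-one, p2-one) picks one side
        best = -np.inf
        for bits in range(8):
            mask = base.copy()
            for j, (a, b) in enumerate([(3, 4), (5, 6), (7, 8)]):
                mask[a if not (bits >> j) & 1 else b] = True
            best = max(best, fn(chrom(mask)).f)
        assert c1.fitness.f == pytest.approx(best)
        assert n_evals <= 5  # L4 rows + composite


def test_oa_children_preserve_mask_weight():
    rng = np.random.default_rng(7)
    weights = rng.normal(size=30)
    fn = additive_fitness(weights)
    for _ in range(50):
        m1 = np.zeros(30, dtype=bool)
        m2 = np.zeros(30, dtype=bool)
        m1[rng.choice(30, 8, replace=False)] = True
        m2[rng.choice(30, 8, replace=False)] = True
        p1, p2 = chrom(m1, g=3, c=9), chrom(m2, g=12, c=2)
        p1.fitness = fn(p1)
        p2.fitness = fn(p2)
        c1, c2, _ = oa_crossover(p1, p2, fn, rng)
        assert c1.r == 8 and c2.r == 8


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------

def test_mutate_full_mask_unchanged():
    ch = chrom([1, 1, 1])
    before = ch.mask.copy()
    mutate(ch, np.random.default_rng(0))
    np.testing.assert_array_equal(ch.mask, before)


def test_mutate_preserves_weight_and_hamming():
    rng = np.random.default_rng(8)
    for _ in range(1000):
        mask = np.zeros(15, dtype=bool)
        mask[rng.choice(15, 6, replace=False)] = True
        ch = chrom(mask.copy())
        mutate(ch, rng)
        assert ch.r == 6
        hamming = int((ch.mask != mask).sum())
        assert hamming in (0, 2)


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def test_run_trivial_full_set(tiny_cohort):
    n = tiny_cohort.n_transcripts
    cfg = GAConfig(r_start=n, r_end=n, pop_size=4, gmax=2, runs=1, w=1.0, seed=0)
    res = ibcga_run(tiny_cohort, cfg, np.random.default_rng(0))
    assert sorted(res.best.transcript_ids) == sorted(tiny_cohort.transcript_ids)


def test_run_respects_evaluation_budget(planted_cohort):
    cohort, _ = planted_cohort
    cfg = GAConfig(r_start=3, r_end=5, pop_size=10, gmax=5, runs=1, w=0.8, seed=1)
    res = ibcga_run(cohort, cfg, np.random.default_rng(1))
    assert res.n_evaluations <= evaluation_budget(cfg)
    # spec-form bound: stages * Gmax * (N_pop + p_c*N_pop*(M+1)/2)
    stages = cfg.r_end - cfg.r_start + 1
    spec_bound = stages * cfg.gmax * (cfg.pop_size + cfg.p_c * cfg.pop_size * 4.5)
    assert res.n_evaluations <= spec_bound


def test_run_stage_masks_have_stage_weight(planted_cohort):
    cohort, _ = planted_cohort
    cfg = GAConfig(r_start=2, r_end=4, pop_size=8, gmax=3, runs=1, w=0.8, seed=2)
    res = ibcga_run(cohort, cfg, np.random.default_rng(2))
    for r, sol in res.stage_solutions.items():
        assert len(sol.transcript_ids) == r


def test_run_deterministic_under_seed(planted_cohort):
    cohort, _ = planted_cohort
    cfg = GAConfig(r_start=2, r_end=3, pop_size=8, gmax=4, runs=2, w=0.8, seed=11)
    a = multi_run(cohort, cfg)
    b = multi_run(cohort, cfg)
    assert [s.transcript_ids for s in a.solutions] == [s.transcript_ids for s in b.solutions]
    assert [(s.gamma_code, s.c_code) for s in a.solutions] == [
        (s.gamma_code, s.c_code) for s in b.solutions
    ]
    assert a.appearance_counts == b.appearance_counts
    assert a.s_a.fitness == b.s_a.fitness and a.s_b.transcript_ids == b.s_b.transcript_ids


def test_config_validation_errors(tiny_cohort):
    with pytest.raises(ValueError):
        ibcga_run(
            tiny_cohort,
            GAConfig(r_start=2, r_end=99, pop_size=4, gmax=1, runs=1),
            np.random.default_rng(0),
        )


def test_multi_run_single_run_sa_equals_sb(planted_cohort):
    cohort, _ = planted_cohort
    cfg = GAConfig(r_start=2, r_end=2, pop_size=8, gmax=3, runs=1, w=0.8, seed=3)
    ens = multi_run(cohort, cfg)
    assert ens.s_a.transcript_ids == ens.s_b.transcript_ids
    assert all(v <= cfg.runs for v in ens.appearance_counts.values())
    assert all(ens.s_a.fitness.f >= s.fitness.f for s in ens.solutions)


def test_w1_ignores_survival_area(planted_cohort):
    """With w=1 the optimizer trajectory is identical when Asurv is constant."""
    cohort, _ = planted_cohort
    cfg = GAConfig(r_start=2, r_end=3, pop_size=10, gmax=4, runs=1, w=1.0, seed=4)

    res_a = ibcga_run(cohort, cfg, np.random.default_rng(4))

    class ConstantAreaEvaluator(FitnessEvaluator):
        def __call__(self, chrom):
            fb = super().__call__(chrom)
            fixed = FitnessBreakdown(acc=fb.acc, asurv=0.123, w=fb.w, f=fb.f)
            chrom.fitness = fixed
            return fixed

    res_b = ibcga_run(
        cohort,
        cfg,
        np.random.default_rng(4),
        evaluator=ConstantAreaEvaluator(cohort, w=1.0),
    )
    assert res_a.best.transcript_ids == res_b.best.transcript_ids
    assert (res_a.best.gamma_code, res_a.best.c_code) == (
        res_b.best.gamma_code,
        res_b.best.c_code,
    )
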