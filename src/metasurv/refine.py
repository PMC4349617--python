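"""Post-GA marker refinement: shortlists, backward selection, univariate views.

After R independent GA runs, transcripts are ranked by how often they were
selected (appearance frequency).  Sequential backward selection (SBS) then
starts from the top-frequency shortlist and repeatedly removes the
transcript whose removal least degrades — or most improves — the weighted
fitness, tracing the whole trajectory down to a single transcript.
Univariate metrics (t-test p, single-transcript SVM accuracy, its
survival-area) and their ranks support the interpretation of a final panel.
The EMT pre-filter reduces a genome-wide cohort to the top differential
transcripts within the EMT regulator categories before any selection runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from metasurv.classify import FitnessBreakdown, SVMParams, grid_search_best
from metasurv.cohort import (
    Cohort,
    DISTANT,
    EMT_CATEGORIES,
    NON_DISTANT,
    SelectionResult,
    TranscriptAnnotation,
)
from metasurv.ibcga import RunEnsemble
from metasurv.survival import default_t_max

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SBSRecord:
    """One step of the backward-selection trajectory."""

    transcript_ids: tuple[str, ...]
    removed: str | None  # transcript removed to arrive at this set
    params: SVMParams
    fitness: FitnessBreakdown


@dataclass
class SBSTrajectory:
    """The full removal trajectory plus the best sets it visited."""

    records: list[SBSRecord]
    best_by_f: SelectionResult
    best_by_asurv: SelectionResult

    def to_tsv(self, path) -> None:
        rows = ["size\tremoved_id\tacc\tasurv\tf"]
        for rec in self.records:
            rows.append(
                f"{len(rec.transcript_ids)}\t{rec.removed or ''}\t"
                f"{rec.fitness.acc:.6f}\t{rec.fitness.asurv:.6f}\t{rec.fitness.f:.6f}"
            )
        from pathlib import Path

        Path(path).write_text("\n".join(rows) + "\n")


@dataclass(frozen=True)
class UnivariateRecord:
    """Single-transcript metrics and their within-batch ranks (1 = best)."""

    transcript_id: str
    t_p_value: float
    single_gene_acc: float
    single_gene_asurv: float
    rank_acc: int
    rank_asurv: int
    rank_p: int


# ---------------------------------------------------------------------------
# appearance aggregation
# ---------------------------------------------------------------------------

def appearance_shortlist(run_ensemble: RunEnsemble, k: int = 30) -> list[str]:
    """Top-k transcripts by appearance count across the R runs.

    Ties break by the higher mean fitness of the solutions containing the
    transcript, then lexicographic id.
    """
    if not run_ensemble.solutions:
        raise ValueError("run ensemble holds no solutions")
    counts = run_ensemble.appearance_counts
    mean_fitness: dict[str, float] = {}
    for t in counts:
        fs = [
            s.fitness.f for s in run_ensemble.solutions if t in s.transcript_ids
        ]
        mean_fitness[t] = float(np.mean(fs))
    ordered = sorted(
        counts, key=lambda t: (-counts[t], -mean_fitness[t], t)
    )
    if k > len(ordered):
        logger.warning(
            "requested top-%d but only %d transcripts were ever selected", k, len(ordered)
        )
        return ordered
    return ordered[:k]


# ---------------------------------------------------------------------------
# univariate metrics
# ---------------------------------------------------------------------------

def _expression_p_value(cohort: Cohort, column: int) -> float:
    """Pooled two-sample t-test p on one transcript; constant columns give 1."""
    x = cohort.expression[:, column]
    a = x[cohort.class_labels == NON_DISTANT]
    b = x[cohort.class_labels == DISTANT]
    if np.ptp(x) == 0 or (np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean()):
        return 1.0
    _, p = stats.ttest_ind(a, b, equal_var=True)
    return 1.0 if np.isnan(p) else float(p)


def _ranks(values: Sequence[float], ids: Sequence[str], descending: bool) -> list[int]:
    """Ranks 1..k; ties broken by lexicographic id for determinism."""
    sign = -1.0 if descending else 1.0
    order = sorted(range(len(values)), key=lambda i: (sign * values[i], ids[i]))
    ranks = [0] * len(values)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return ranks


def univariate_rank(
    cohort: Cohort, transcripts: Sequence[str], t_max: float | None = None
) -> list[UnivariateRecord]:
    """Per-transcript p-value, single-gene SVM accuracy and survival area.

    The accuracy is the grid-searched LOOCV accuracy of an SVM on that
    transcript alone (w = 1); the survival area comes from that
    classifier's predicted groups.  Rank 1 marks the highest accuracy, the
    largest area, and the smallest p, respectively.
    """
    if t_max is None:
        t_max = default_t_max(cohort)
    cols = cohort.transcript_indices(list(transcripts))
    pvals, accs, areas = [], [], []
    for t, c in zip(transcripts, cols):
        pvals.append(_expression_p_value(cohort, c))
        _, fb = grid_search_best(cohort, [t], w=1.0, t_max=t_max)
        accs.append(fb.acc)
        areas.append(fb.asurv)
    ids = list(transcripts)
    rank_acc = _ranks(accs, ids, descending=True)
    rank_asurv = _ranks(areas, ids, descending=True)
    rank_p = _ranks(pvals, ids, descending=False)
    return [
        UnivariateRecord(
            transcript_id=t,
            t_p_value=pvals[i],
            single_gene_acc=accs[i],
            single_gene_asurv=areas[i],
            rank_acc=rank_acc[i],
            rank_asurv=rank_asurv[i],
            rank_p=rank_p[i],
        )
        for i, t in enumerate(ids)
    ]


def rank_correlation(ranks_a: Sequence[float], ranks_b: Sequence[float]) -> float:
    """Pearson correlation between two equal-length rank vectors."""
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rank vectors must be 1-D and equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank vectors must have nonzero variance")
    return float(stats.pearsonr(a, b)[0])


# ---------------------------------------------------------------------------
# sequential backward selection
# ---------------------------------------------------------------------------

def sbs(
    start_set: Sequence[str],
    cohort: Cohort,
    w: float,
    t_max: float | None = None,
) -> SBSTrajectory:
    """Greedy backward elimination from ``start_set`` down to one transcript.

    At each step every single-removal candidate set G - x is scored with a
    full hyperparameter grid search; the removal with the largest f(G - x)
    wins (removals may *increase* f).  Ties remove the transcript with the
    larger univariate p (least individually informative), then the
    lexicographically larger id.  Returns the trajectory and the visited
    sets maximizing f and the survival area.
    """
    G = list(dict.fromkeys(start_set))
    if not G:
        raise ValueError("start set must be nonempty")
    if t_max is None:
        t_max = default_t_max(cohort)
    pval = {
        t: _expression_p_value(cohort, c)
        for t, c in zip(G, cohort.transcript_indices(G))
    }

    params, fb = grid_search_best(cohort, G, w=w, t_max=t_max)
    records = [SBSRecord(tuple(G), None, params, fb)]
    while len(G) > 1:
        candidates = []
        for x in G:
            reduced = [t for t in G if t != x]
            p_x, fb_x = grid_search_best(cohort, reduced, w=w, t_max=t_max)
            candidates.append((x, reduced, p_x, fb_x))
        # largest f; ties -> larger univariate p, then larger id removed
        x, reduced, p_x, fb_x = max(
            candidates, key=lambda c: (c[3].f, pval[c[0]], c[0])
        )
        records.append(SBSRecord(tuple(reduced), x, p_x, fb_x))
        G = reduced
        logger.info("sbs removed %s -> size %d, f=%.4f", x, len(G), fb_x.f)

    def to_result(rec: SBSRecord, tag: str) -> SelectionResult:
        return SelectionResult(
            transcript_ids=list(rec.transcript_ids),
            fitness=rec.fitness,
            gamma_code=rec.params.gamma_code,
            c_code=rec.params.c_code,
            provenance=f"sbs {tag}, size {len(rec.transcript_ids)}",
        )

    best_f = max(records, key=lambda r: r.fitness.f)
    best_asurv = max(records, key=lambda r: r.fitness.asurv)
    return SBSTrajectory(
        records=records,
        best_by_f=to_result(best_f, "best-by-f"),
        best_by_asurv=to_result(best_asurv, "best-by-asurv"),
    )


# ---------------------------------------------------------------------------
# EMT category pre-filter
# ---------------------------------------------------------------------------

def emt_filter(
    cohort: Cohort,
    annotation: Iterable[TranscriptAnnotation],
    categories: Sequence[str] = EMT_CATEGORIES,
    k: int = 474,
) -> Cohort:
    """Keep EMT-category transcripts, then the k most differential by p.

    Transcripts without an annotation record count as category ``other``.
    Ranking is by pooled two-sample t-test p ascending (ties by id); the
    sample order of the cohort is preserved.
    """
    cat_of = {a.transcript_id: a.regulator_type for a in annotation}
    categories = set(categories)
    survivors = [
        (t, i)
        for i, t in enumerate(cohort.transcript_ids)
        if cat_of.get(t, "other") in categories
    ]
    if not survivors:
        raise ValueError("no transcripts survive the category filter")
    scored = sorted(
        survivors, key=lambda ti: (_expression_p_value(cohort, ti[1]), ti[0])
    )
    kept = [t for t, _ in scored[: min(k, len(scored))]]
    # preserve original column order within the kept set
    kept_in_order = [t for t in cohort.transcript_ids if t in set(kept)]
    return cohort.subset_transcripts(kept_in_order)
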