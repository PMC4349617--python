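"""Synthetic cohorts with the structure the selection method assumes.

The generator emulates a two-class lung-cancer cohort: a small planted
subset of transcripts is differentially expressed between the distant- and
non-distant-metastasis classes, and the two classes have strongly separated
disease-free survival.  Distant-metastasis patients relapse early (observed
events, exponential times truncated at the follow-up horizon); non-distant
patients have long latent times that are mostly censored within a uniform
follow-up window — reproducing the heavy censoring asymmetry of real
surgical cohorts.  Class membership drives expression and survival
independently; there is no expression-survival link beyond the class, which
is exactly the dependence structure the weighted fitness exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from metasurv.cohort import (
    Cohort,
    DISTANT,
    EMT_CATEGORIES,
    EVENT,
    NON_DISTANT,
    TranscriptAnnotation,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings (defaults mirror the training-cohort structure).

    ``effect_size`` is the class-mean shift of informative transcripts in
    noise-SD units; survival means are the latent exponential means in
    months; non-distant follow-up is censored uniformly inside
    ``censor_window``.
    """

    n_samples: int = 78
    n_transcripts: int = 474
    n_informative: int = 10
    n_non_distant: int = 37
    n_distant: int = 41
    effect_size: float = 1.5
    noise_sd: float = 1.0
    mean_dfs_non_distant: float = 90.0
    mean_dfs_distant: float = 14.0
    horizon: float = 120.0
    censor_window: tuple[float, float] = (60.0, 120.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative > self.n_transcripts:
            raise ValueError("n_informative cannot exceed n_transcripts")
        if self.n_non_distant + self.n_distant != self.n_samples:
            raise ValueError("class sizes must sum to n_samples")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.mean_dfs_non_distant <= self.mean_dfs_distant:
            raise ValueError("non-distant survival mean must exceed the distant mean")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.censor_window
        if not 0 < lo <= hi <= self.horizon:
            raise ValueError("censor window must satisfy 0 < lo <= hi <= horizon")


def _simulate(
    config: SimulationConfig,
    rng: np.random.Generator,
    informative_idx: np.ndarray,
    sample_prefix: str,
) -> Cohort:
    n, p = config.n_samples, config.n_transcripts
    labels = np.concatenate(
        (
            np.full(config.n_non_distant, NON_DISTANT),
            np.full(config.n_distant, DISTANT),
        )
    )
    expression = rng.normal(0.0, config.noise_sd, size=(n, p))
    shift = config.effect_size * config.noise_sd
    for j in informative_idx:
        expression[labels == DISTANT, j] += shift

    dfs = np.empty(n)
    events = np.empty(n, dtype=int)
    distant = labels == DISTANT
    n_m = int(distant.sum())
    dfs[distant] = np.minimum(
        rng.exponential(config.mean_dfs_distant, size=n_m), config.horizon
    )
    events[distant] = EVENT
    n_nm = n - n_m
    latent = rng.exponential(config.mean_dfs_non_distant, size=n_nm)
    censor = rng.uniform(*config.censor_window, size=n_nm)
    cutoff = np.minimum(censor, config.horizon)
    dfs[~distant] = np.minimum(latent, cutoff)
    events[~distant] = (latent <= cutoff).astype(int)

    return Cohort(
        sample_ids=[f"{sample_prefix}{i + 1:03d}" for i in range(n)],
        expression=expression,
        transcript_ids=[f"T{j + 1:04d}" for j in range(p)],
        class_labels=labels,
        dfs_months=dfs,
        event_flags=events,
    )


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, list[str]]:
    """Draw one cohort; returns it with the planted informative transcript ids."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    informative_idx = np.sort(
        rng.choice(config.n_transcripts, size=config.n_informative, replace=False)
    )
    cohort = _simulate(config, rng, informative_idx, sample_prefix="S")
    informative = [cohort.transcript_ids[j] for j in informative_idx]
    return cohort, informative


def make_paperlike_pair(
    config: SimulationConfig,
    n_test: int = 26,
    test_balance: tuple[int, int] = (6, 20),
) -> tuple[Cohort, Cohort, list[str]]:
    """A training cohort plus an independent test cohort (same process).

    The test cohort shares the transcript panel and the planted informative
    set, has disjoint sample ids, and defaults to the 6:20 class balance of
    a small validation series.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    informative_idx = np.sort(
        rng.choice(config.n_transcripts, size=config.n_informative, replace=False)
    )
    train = _simulate(config, rng, informative_idx, sample_prefix="TR")
    test_cfg = replace(
        config,
        n_samples=n_test,
        n_non_distant=test_balance[0],
        n_distant=test_balance[1],
    )
    test = _simulate(test_cfg, rng, informative_idx, sample_prefix="TE")
    informative = [train.transcript_ids[j] for j in informative_idx]
    return train, test, informative


def simulate_annotation(
    transcript_ids: list[str],
    informative_ids: list[str] | None = None,
    seed: int = 0,
    emt_fraction: float = 0.8,
) -> list[TranscriptAnnotation]:
    """Random regulator-category annotation for a synthetic transcript panel.

    Planted informative transcripts always land in an EMT category so that
    the category pre-filter cannot silently discard the signal; the rest
    are EMT with probability ``emt_fraction`` and ``other`` otherwise.
    """
    rng = np.random.default_rng(seed)
    informative = set(informative_ids or [])
    records = []
    for t in transcript_ids:
        if t in informative or rng.random() < emt_fraction:
            category = EMT_CATEGORIES[rng.integers(len(EMT_CATEGORIES))]
        else:
            category = "other"
        records.append(
            TranscriptAnnotation(
                transcript_id=t, gene_symbol=f"GENE_{t}", regulator_type=category
            )
        )
    return records
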