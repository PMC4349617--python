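import numpy as np
import pytest

from metasurv.cohort import Cohort
from metasurv.simulate import SimulationConfig, simulate_cohort


def make_cohort(
    n_samples: int = 20,
    n_transcripts: int = 4,
    seed: int = 0,
    separation: float = 0.0,
) -> Cohort:
    """Small hand-rolled cohort; `separation` shifts class means on all columns."""
    rng = np.random.default_rng(seed)
    labels = np.array([0, 1] * (n_samples // 2) + [0] * (n_samples % 2))
    X = rng.normal(size=(n_samples, n_transcripts))
    X[labels == 1] += separation
    dfs = np.where(labels == 1, rng.uniform(2, 30, n_samples), rng.uniform(40, 110, n_samples))
    events = np.where(labels == 1, 1, (rng.random(n_samples) < 0.3).astype(int))
    return Cohort(
        sample_ids=[f"P{i:02d}" for i in range(n_samples)],
        expression=X,
        transcript_ids=[f"G{j}" for j in range(n_transcripts)],
        class_labels=labels,
        dfs_months=dfs,
        event_flags=events,
    )


@pytest.fixture
def tiny_cohort() -> Cohort:
    return make_cohort(n_samples=12, n_transcripts=3, seed=1)


@pytest.fixture
def separable_cohort() -> Cohort:
    """Two well-separated Gaussian clusters, 20 samples, 2 features."""
    return make_cohort(n_samples=20, n_transcripts=2, seed=2, separation=6.0)


@pytest.fixture
def planted_cohort() -> tuple[Cohort, list[str]]:
    cfg = SimulationConfig(
        n_samples=40,
        n_transcripts=30,
        n_informative=3,
        n_non_distant=19,
        n_distant=21,
        effect_size=2.0,
        seed=7,
    )
    return simulate_cohort(cfg)
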