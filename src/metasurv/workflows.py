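"""Higher-level experiment orchestration shared by the CLI and scripts."""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from metasurv.classify import svm_train_predict
from metasurv.cohort import Cohort
from metasurv.ibcga import GAConfig, multi_run

logger = logging.getLogger(__name__)


def _take_samples(cohort: Cohort, idx: np.ndarray) -> Cohort:
    return Cohort(
        sample_ids=[cohort.sample_ids[i] for i in idx],
        expression=cohort.expression[idx],
        transcript_ids=list(cohort.transcript_ids),
        class_labels=cohort.class_labels[idx],
        dfs_months=cohort.dfs_months[idx],
        event_flags=cohort.event_flags[idx],
    )


def select_and_test(
    train: Cohort, test: Cohort, config: GAConfig
) -> tuple[float, float]:
    """Run the GA selection on ``train``, evaluate its best set on ``test``.

    Returns (training fitness f of the chosen set, test accuracy of a
    single SVM with the set's own hyperparameter codes).
    """
    ensemble = multi_run(train, config)
    best = ensemble.s_a
    from metasurv.classify import SVMParams

    params = SVMParams(best.gamma_code, best.c_code)
    _, acc = svm_train_predict(train, test, best.transcript_ids, params)
    return best.fitness.f, acc


def weight_sweep(
    cohort: Cohort,
    weights: tuple[float, ...] = (1.0, 0.8, 0.5, 0.2),
    folds: int = 5,
    config: GAConfig | None = None,
    seed: int = 0,
) -> dict[float, float]:
    """Mean held-out accuracy of the selection pipeline per fitness weight.

    The cohort is split into stratified folds (class proportions
    preserved); each fold serves as the test set once while the GA selects
    a transcript set on the remaining folds; the per-weight mean test
    accuracy is returned.  The GA budget comes from ``config``.
    """
    if config is None:
        config = GAConfig()
    labels = cohort.class_labels
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(labels)), labels))
    for train_idx, _ in splits:
        if len(np.unique(labels[train_idx])) < 2:
            raise ValueError("a training split lacks one class; use fewer folds")

    results: dict[float, float] = {}
    for w in weights:
        accs = []
        for fold, (train_idx, test_idx) in enumerate(splits):
            fold_cfg = replace(config, w=w, seed=(config.seed + 1000 * fold) % 2**31)
            train = _take_samples(cohort, train_idx)
            test = _take_samples(cohort, test_idx)
            _, acc = select_and_test(train, test, fold_cfg)
            accs.append(acc)
            logger.info("w=%.2f fold %d test acc %.4f", w, fold, acc)
        results[w] = float(np.mean(accs))
    return results
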