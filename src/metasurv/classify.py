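"""RBF-SVM training and evaluation, the weighted fitness, ensembles, SVR.

Hyperparameters live on a 4-bit log2 grid: gamma, C in {2^-7, ..., 2^8},
encoded as integers 0..15 with value 2^(code-7).  The selection fitness is

    f(G) = w * Acc + (1 - w) * max(Asurv, 0)

where Acc is the leave-one-out cross-validation accuracy of an RBF-SVM on
the transcript set G and Asurv is the signed normalized area between the
Kaplan-Meier disease-free-survival curves of the two *predicted* groups
(predicted non-distant on top).  A negative signed area contributes zero
but is recorded for diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC, SVR, _libsvm

from metasurv.cohort import Cohort, DISTANT
from metasurv.survival import asurv_from_labels, default_t_max

logger = logging.getLogger(__name__)

_libsvm.set_verbosity_wrap(0)  # silence libsvm's per-fit console output

GRID_CODES = range(16)


def decode_log2_param(code: int) -> float:
    """Map a 4-bit grid code to its hyperparameter value 2^(code-7)."""
    code = int(code)
    if not 0 <= code <= 15:
        raise ValueError(f"grid code must be in 0..15, got {code}")
    return float(2.0 ** (code - 7))


@dataclass(frozen=True)
class SVMParams:
    """RBF-SVM hyperparameters on the 4-bit log2 grid."""

    gamma_code: int
    c_code: int

    def __post_init__(self) -> None:
        decode_log2_param(self.gamma_code)
        decode_log2_param(self.c_code)

    @property
    def gamma(self) -> float:
        return decode_log2_param(self.gamma_code)

    @property
    def C(self) -> float:
        return decode_log2_param(self.c_code)


@dataclass(frozen=True)
class FitnessBreakdown:
    """The (Acc, Asurv, w, f) quadruple for a candidate transcript set.

    ``asurv`` is the signed area; the clamp to [0, 1] happens inside ``f``.
    """

    acc: float
    asurv: float
    w: float
    f: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.acc <= 1.0:
            raise ValueError("acc must lie in [0, 1]")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        expected = self.w * self.acc + (1.0 - self.w) * max(self.asurv, 0.0)
        if abs(self.f - expected) > 1e-9:
            raise ValueError("f must equal w*acc + (1-w)*max(asurv, 0)")

    @staticmethod
    def compute(acc: float, asurv: float, w: float) -> "FitnessBreakdown":
        f = w * acc + (1.0 - w) * max(asurv, 0.0)
        return FitnessBreakdown(acc=float(acc), asurv=float(asurv), w=float(w), f=float(f))


@dataclass(frozen=True)
class EnsembleModel:
    """A random-subspace committee of RBF-SVMs combined by majority vote."""

    members: tuple[tuple[tuple[str, ...], SVMParams], ...]
    tie_break: int = DISTANT


# ---------------------------------------------------------------------------
# LOOCV internals (precomputed-kernel path shared by the grid search)
# ---------------------------------------------------------------------------

def _pairwise_sq_dists(X: np.ndarray) -> np.ndarray:
    sq = np.einsum("ij,ij->i", X, X)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(D, 0.0, out=D)
    return D


def _loocv_per_fold(K: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    """Reference LOOCV: one explicit SVC fit per held-out sample."""
    n = y.size
    preds = np.empty(n, dtype=int)
    idx = np.arange(n)
    warned = False
    for i in range(n):
        tr = idx != i
        ytr = y[tr]
        if np.all(ytr == ytr[0]):
            # one-class training fold: predict the (majority = only) class
            if not warned:
                logger.warning("LOOCV fold %d has a single class; predicting it", i)
                warned = True
            preds[i] = ytr[0]
            continue
        svc = SVC(C=C, kernel="precomputed")
        svc.fit(K[np.ix_(tr, tr)], ytr)
        preds[i] = svc.predict(K[i, tr][None, :])[0]
    return preds


def _loocv_precomputed(K: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    """Leave-one-out predictions for an SVM with a precomputed kernel.

    Uses libsvm's built-in n-fold cross-validation (n folds = exact,
    deterministic leave-one-out; verified against the per-fold path) unless
    a class has fewer than two members, in which case one-class training
    folds can arise and the per-fold path with its majority convention is
    used instead.
    """
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < 2:
        return _loocv_per_fold(K, y, C)
    target = _libsvm.cross_validation(
        np.ascontiguousarray(K, dtype=np.float64),
        y.astype(np.float64),
        y.size,
        svm_type=0,
        kernel="precomputed",
        C=C,
    )
    return target.astype(int)


def _fitness_from_predictions(
    cohort: Cohort, preds: np.ndarray, w: float, t_max: float
) -> FitnessBreakdown:
    acc = float(np.mean(preds == cohort.class_labels))
    area = asurv_from_labels(cohort, preds, t_max).signed_area_fraction
    return FitnessBreakdown.compute(acc, area, w)


def _resolve_columns(cohort: Cohort, G: Sequence[str] | np.ndarray) -> np.ndarray:
    """Accept transcript ids or integer column indices."""
    arr = np.asarray(G)
    if arr.dtype.kind in "iu":
        return arr.astype(int)
    return cohort.transcript_indices([str(g) for g in G])


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def loocv_predict(
    cohort: Cohort, G: Sequence[str] | np.ndarray, params: SVMParams
) -> tuple[np.ndarray, float]:
    """Leave-one-out predicted classes and accuracy for a transcript set."""
    cols = _resolve_columns(cohort, G)
    if cols.size == 0:
        raise ValueError("transcript set must be nonempty")
    cohort.require_both_classes()
    D = _pairwise_sq_dists(cohort.expression[:, cols])
    K = np.exp(-params.gamma * D)
    preds = _loocv_precomputed(K, cohort.class_labels, params.C)
    acc = float(np.mean(preds == cohort.class_labels))
    return preds, acc


def fitness_eval(
    cohort: Cohort,
    G: Sequence[str] | np.ndarray,
    params: SVMParams,
    w: float,
    t_max: float | None = None,
) -> FitnessBreakdown:
    """Weighted fitness of a transcript set at fixed SVM hyperparameters.

    Asurv is computed from the LOOCV-*predicted* group memberships, not the
    true labels: the statistic scores how well the candidate classifier's
    groups separate survival.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    if t_max is None:
        t_max = default_t_max(cohort)
    preds, _ = loocv_predict(cohort, G, params)
    return _fitness_from_predictions(cohort, preds, w, t_max)


def grid_search_best(
    cohort: Cohort,
    G: Sequence[str] | np.ndarray,
    w: float,
    t_max: float | None = None,
) -> tuple[SVMParams, FitnessBreakdown]:
    """Exhaustive 16 x 16 grid search over (gamma_code, c_code).

    Among equal-fitness cells the smallest ``c_code`` wins, then the
    smallest ``gamma_code`` (prefers smoother models, deterministically).
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    cols = _resolve_columns(cohort, G)
    if cols.size == 0:
        raise ValueError("transcript set must be nonempty")
    cohort.require_both_classes()
    if t_max is None:
        t_max = default_t_max(cohort)
    D = _pairwise_sq_dists(cohort.expression[:, cols])
    y = cohort.class_labels

    breakdowns: dict[tuple[int, int], FitnessBreakdown] = {}
    fvals = np.empty((16, 16))
    for gamma_code in GRID_CODES:
        K = np.exp(-decode_log2_param(gamma_code) * D)
        for c_code in GRID_CODES:
            preds = _loocv_precomputed(K, y, decode_log2_param(c_code))
            fb = _fitness_from_predictions(cohort, preds, w, t_max)
            breakdowns[(gamma_code, c_code)] = fb
            fvals[gamma_code, c_code] = fb.f
    fmax = fvals.max()
    ties = np.argwhere(fvals == fmax)
    # minimal (c_code, gamma_code) among ties
    order = np.lexsort((ties[:, 0], ties[:, 1]))
    gamma_code, c_code = (int(v) for v in ties[order[0]])
    params = SVMParams(gamma_code=gamma_code, c_code=c_code)
    return params, breakdowns[(gamma_code, c_code)]


def svm_train_predict(
    train: Cohort,
    test: Cohort,
    G: Sequence[str],
    params: SVMParams,
) -> tuple[np.ndarray, float]:
    """Train one RBF-SVM on ``train`` and classify ``test``."""
    Xtr = train.expression[:, train.transcript_indices(list(G))]
    Xte = test.expression[:, test.transcript_indices(list(G))]
    svc = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
    svc.fit(Xtr, train.class_labels)
    preds = svc.predict(Xte).astype(int)
    acc = float(np.mean(preds == test.class_labels))
    return preds, acc


def ensemble_train_predict(
    train: Cohort,
    test: Cohort,
    G: Sequence[str],
    n_members: int = 30,
    member_size: int = 5,
    seed: int = 0,
    t_max: float | None = None,
) -> tuple[np.ndarray, float, EnsembleModel]:
    """Random-subspace SVM ensemble: train on ``train``, vote on ``test``.

    Each member draws ``member_size`` transcripts uniformly without
    replacement from ``G`` (independently across members), tunes its own
    grid-searched hyperparameters on the training cohort, and the final
    label is the majority vote with 50:50 ties broken toward ``distant``.
    """
    G = list(G)
    if member_size > len(G):
        raise ValueError(
            f"member_size {member_size} exceeds transcript set size {len(G)}"
        )
    test.transcript_indices(G)  # raises if the test cohort lacks any
    rng = np.random.default_rng(seed)
    members = []
    votes = np.zeros((n_members, test.n_samples), dtype=int)
    for j in range(n_members):
        subset = [G[i] for i in rng.choice(len(G), size=member_size, replace=False)]
        params, _ = grid_search_best(train, subset, w=1.0, t_max=t_max)
        preds, _ = svm_train_predict(train, test, subset, params)
        votes[j] = preds
        members.append((tuple(subset), params))
    distant_votes = votes.sum(axis=0)
    preds = np.where(distant_votes * 2 >= n_members, DISTANT, 1 - DISTANT)
    acc = float(np.mean(preds == test.class_labels))
    return preds, acc, EnsembleModel(members=tuple(members))


SVR_EPSILON = 0.1  # months; fixed so the hyperparameter search stays 2-D


def svr_fit_predict(
    train: Cohort, G: Sequence[str]
) -> tuple[np.ndarray, float, float]:
    """Support-vector regression of DFS months on a transcript set.

    Epsilon-insensitive SVR with RBF kernel.  Gamma and C are grid-searched
    over the classification grid by leave-one-out cross-validated MAE
    (choosing them on the training fit would always favor the pure
    interpolator); the winning model is then fitted on the full training
    cohort and evaluated on it.  Returns (per-sample training predictions,
    training MAE in months, Pearson R between predicted and observed).
    """
    cols = _resolve_columns(train, G)
    if cols.size == 0:
        raise ValueError("transcript set must be nonempty")
    y = train.dfs_months.astype(np.float64)
    if np.ptp(y) == 0:
        raise ValueError("survival times are constant; SVR target is degenerate")
    X = np.ascontiguousarray(train.expression[:, cols], dtype=np.float64)

    cv_maes = np.empty((16, 16))
    for gamma_code in GRID_CODES:
        for c_code in GRID_CODES:
            loo = _libsvm.cross_validation(
                X, y, y.size,
                svm_type=3,  # epsilon-SVR
                kernel="rbf",
                gamma=decode_log2_param(gamma_code),
                C=decode_log2_param(c_code),
                epsilon=SVR_EPSILON,
            )
            cv_maes[gamma_code, c_code] = float(np.mean(np.abs(loo - y)))
    mmin = cv_maes.min()
    ties = np.argwhere(cv_maes == mmin)
    order = np.lexsort((ties[:, 0], ties[:, 1]))
    gamma_code, c_code = (int(v) for v in ties[order[0]])

    model = SVR(
        kernel="rbf",
        gamma=decode_log2_param(gamma_code),
        C=decode_log2_param(c_code),
        epsilon=SVR_EPSILON,
    )
    pred = model.fit(X, y).predict(X)
    mae = float(np.mean(np.abs(pred - y)))
    r = float(np.corrcoef(pred, y)[0, 1])
    return pred, mae, r
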