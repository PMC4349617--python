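"""Domain types and TSV/JSON readers and writers for cohorts and results.

A cohort pairs a normalized log-scale expression matrix (samples x
transcripts) with per-sample clinical records: the binary metastasis class
(distant vs non-distant), the disease-free survival time in months, and an
event/censor flag.  Expression values are taken as-is; normalization is
assumed to have happened upstream.

File layouts
------------
Expression TSV: header ``sample_id`` followed by one column per transcript;
one row per sample.  Clinical TSV: columns ``sample_id``, ``metastasis``
(1 = distant, 0 = non-distant), ``dfs_months``, ``event`` (1 = event,
0 = censored).  Annotation TSV: ``transcript_id``, ``gene_symbol``,
``regulator_type``.  Selection results are JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: class-label encoding used throughout the package
DISTANT = 1
NON_DISTANT = 0

#: event-flag encoding
EVENT = 1
CENSORED = 0

#: closed vocabulary of regulator categories; the first five are the
#: epithelial-mesenchymal-transition (EMT) regulator classes used by the
#: candidate-transcript pre-filter.
EMT_CATEGORIES = (
    "growth factor",
    "ligand-dependent nuclear receptor",
    "transcription regulator",
    "cytokine",
    "kinase",
)
REGULATOR_TYPES = EMT_CATEGORIES + ("other",)


class CohortError(ValueError):
    """Raised on malformed or inconsistent cohort input."""


@dataclass
class Cohort:
    """An expression matrix joined with clinical survival records.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers, in expression-file row order.
    expression : ndarray, shape (n_samples, n_transcripts)
        Normalized log-scale intensities; finite floats.
    transcript_ids : list of str
        Unique transcript identifiers (columns of ``expression``).
    class_labels : ndarray of int
        Per-sample metastasis class; 1 = distant, 0 = non-distant.
    dfs_months : ndarray of float
        Disease-free survival time in months (>= 0).
    event_flags : ndarray of int
        1 = event observed, 0 = censored.
    """

    sample_ids: list[str]
    expression: np.ndarray
    transcript_ids: list[str]
    class_labels: np.ndarray
    dfs_months: np.ndarray
    event_flags: np.ndarray

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.class_labels = np.asarray(self.class_labels, dtype=int)
        self.dfs_months = np.asarray(self.dfs_months, dtype=float)
        self.event_flags = np.asarray(self.event_flags, dtype=int)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        n, p = self.expression.shape if self.expression.ndim == 2 else (0, 0)
        if self.expression.ndim != 2:
            raise CohortError("expression must be a 2-D samples x transcripts matrix")
        if len(self.sample_ids) != n:
            raise CohortError(
                f"expression has {n} rows but {len(self.sample_ids)} sample ids"
            )
        if len(self.transcript_ids) != p:
            raise CohortError(
                f"expression has {p} columns but {len(self.transcript_ids)} transcript ids"
            )
        if len(set(self.sample_ids)) != n:
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise CohortError(f"duplicate sample id(s): {dupes}")
        if len(set(self.transcript_ids)) != p:
            raise CohortError("duplicate transcript ids")
        if not np.all(np.isfinite(self.expression)):
            raise CohortError("expression contains non-finite values")
        for name, arr in (
            ("class_labels", self.class_labels),
            ("dfs_months", self.dfs_months),
            ("event_flags", self.event_flags),
        ):
            if arr.shape != (n,):
                raise CohortError(f"{name} must have one entry per sample")
        if not np.all(np.isin(self.class_labels, (DISTANT, NON_DISTANT))):
            raise CohortError("class labels must be 0 (non-distant) or 1 (distant)")
        if not np.all(np.isin(self.event_flags, (EVENT, CENSORED))):
            raise CohortError("event flags must be 0 (censored) or 1 (event)")
        if np.any(self.dfs_months < 0) or not np.all(np.isfinite(self.dfs_months)):
            raise CohortError("dfs_months must be finite and >= 0")

    # -- convenience -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    def require_both_classes(self) -> None:
        """Training cohorts must contain both classes."""
        if len(np.unique(self.class_labels)) < 2:
            raise CohortError("cohort must contain both classes for training")

    def transcript_indices(self, transcripts: Sequence[str]) -> np.ndarray:
        """Column indices of the named transcripts, in the given order."""
        pos = {t: i for i, t in enumerate(self.transcript_ids)}
        missing = [t for t in transcripts if t not in pos]
        if missing:
            raise CohortError(f"transcripts not in cohort: {missing}")
        return np.array([pos[t] for t in transcripts], dtype=int)

    def subset_transcripts(self, transcripts: Sequence[str]) -> "Cohort":
        """A new cohort restricted to the given transcript columns."""
        idx = self.transcript_indices(transcripts)
        return Cohort(
            sample_ids=list(self.sample_ids),
            expression=self.expression[:, idx].copy(),
            transcript_ids=list(transcripts),
            class_labels=self.class_labels.copy(),
            dfs_months=self.dfs_months.copy(),
            event_flags=self.event_flags.copy(),
        )

    def equals(self, other: "Cohort") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.transcript_ids == other.transcript_ids
            and np.allclose(self.expression, other.expression)
            and np.array_equal(self.class_labels, other.class_labels)
            and np.allclose(self.dfs_months, other.dfs_months)
            and np.array_equal(self.event_flags, other.event_flags)
        )


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Regulator-category annotation for one transcript."""

    transcript_id: str
    gene_symbol: str
    regulator_type: str

    def __post_init__(self) -> None:
        if self.regulator_type not in REGULATOR_TYPES:
            raise CohortError(
                f"unknown regulator_type {self.regulator_type!r}; "
                f"expected one of {REGULATOR_TYPES}"
            )


@dataclass
class SelectionResult:
    """A selected transcript set with its fitness and hyperparameter codes.

    ``fitness`` is a :class:`~metasurv.classify.FitnessBreakdown`;
    ``gamma_code`` and ``c_code`` are the 4-bit grid codes of the RBF-SVM
    hyperparameters (gamma = 2^(code-7), C = 2^(code-7)).  ``provenance`` is
    free text recording seed, stage and method tag.
    """

    transcript_ids: list[str]
    fitness: "FitnessBreakdown"
    gamma_code: int
    c_code: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.transcript_ids:
            raise CohortError("SelectionResult requires a nonempty transcript list")
        for code, name in ((self.gamma_code, "gamma_code"), (self.c_code, "c_code")):
            if not 0 <= int(code) <= 15:
                raise CohortError(f"{name} must be in 0..15, got {code}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_cohort(expression_path: str | Path, clinical_path: str | Path) -> Cohort:
    """Load a cohort from an expression TSV and a clinical TSV.

    Sample order follows the expression file.  The two files must describe
    exactly the same set of samples.
    """
    expression_path, clinical_path = Path(expression_path), Path(clinical_path)
    expr = pd.read_csv(expression_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in expr.columns:
        raise CohortError(f"{expression_path}: missing 'sample_id' column")
    clin = pd.read_csv(clinical_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "metastasis", "dfs_months", "event"}
    missing_cols = required - set(clin.columns)
    if missing_cols:
        raise CohortError(f"{clinical_path}: missing columns {sorted(missing_cols)}")

    expr_ids = expr["sample_id"].tolist()
    clin_ids = set(clin["sample_id"])
    only_expr = [s for s in expr_ids if s not in clin_ids]
    only_clin = sorted(clin_ids - set(expr_ids))
    if only_expr or only_clin:
        raise CohortError(
            f"sample mismatch between files: missing from clinical={only_expr}, "
            f"missing from expression={only_clin}"
        )

    matrix = expr.drop(columns="sample_id")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(matrix.columns):
            coerced = pd.to_numeric(matrix[col], errors="coerce")
            bad = coerced.isna() & matrix[col].notna()
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise CohortError(
                    f"{expression_path}: non-numeric expression value "
                    f"{matrix[col].iloc[i]!r} at row {i + 2}, column {col!r}"
                )
        values = matrix.apply(pd.to_numeric).to_numpy()

    clin = clin.set_index("sample_id").loc[expr_ids]
    return Cohort(
        sample_ids=expr_ids,
        expression=values.astype(float),
        transcript_ids=[str(c) for c in matrix.columns],
        class_labels=clin["metastasis"].to_numpy(dtype=int),
        dfs_months=clin["dfs_months"].to_numpy(dtype=float),
        event_flags=clin["event"].to_numpy(dtype=int),
    )


def write_cohort(
    cohort: Cohort, expression_path: str | Path, clinical_path: str | Path
) -> None:
    """Write a cohort to the standard TSV pair (inverse of :func:`read_cohort`)."""
    expr = pd.DataFrame(cohort.expression, columns=cohort.transcript_ids)
    expr.insert(0, "sample_id", cohort.sample_ids)
    expr.to_csv(expression_path, sep="\t", index=False)
    clin = pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "metastasis": cohort.class_labels,
            "dfs_months": cohort.dfs_months,
            "event": cohort.event_flags,
        }
    )
    clin.to_csv(clinical_path, sep="\t", index=False)


def read_annotation(path: str | Path) -> list[TranscriptAnnotation]:
    """Load transcript annotation records from TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"transcript_id", "gene_symbol", "regulator_type"}
    missing = required - set(df.columns)
    if missing:
        raise CohortError(f"{path}: missing annotation columns {sorted(missing)}")
    if df["transcript_id"].duplicated().any():
        dupes = df.loc[df["transcript_id"].duplicated(), "transcript_id"].tolist()
        raise CohortError(f"{path}: duplicate transcript_id(s): {dupes}")
    return [
        TranscriptAnnotation(r.transcript_id, r.gene_symbol, r.regulator_type)
        for r in df.itertuples(index=False)
    ]


def write_annotation(records: Sequence[TranscriptAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "gene_symbol": [r.gene_symbol for r in records],
            "regulator_type": [r.regulator_type for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def write_result(result: SelectionResult, path: str | Path) -> None:
    """Serialize a selection result to JSON (lossless round trip)."""
    from metasurv.classify import FitnessBreakdown  # local to avoid cycle

    fb = result.fitness
    payload = {
        "transcript_ids": result.transcript_ids,
        "fitness": {"acc": fb.acc, "asurv": fb.asurv, "w": fb.w, "f": fb.f},
        "gamma_code": result.gamma_code,
        "c_code": result.c_code,
        "provenance": result.provenance,
    }
    Path(path).write_text(json.dumps(payload, ensure_ascii=False, indent=1))


def read_result(path: str | Path) -> SelectionResult:
    """Load a selection result written by :func:`write_result`."""
    from metasurv.classify import FitnessBreakdown

    try:
        payload = json.loads(Path(path).read_text())
        fb = payload["fitness"]
        return SelectionResult(
            transcript_ids=list(payload["transcript_ids"]),
            fitness=FitnessBreakdown(
                acc=fb["acc"], asurv=fb["asurv"], w=fb["w"], f=fb["f"]
            ),
            gamma_code=int(payload["gamma_code"]),
            c_code=int(payload["c_code"]),
            provenance=payload.get("provenance", ""),
        )
    except (KeyError, json.JSONDecodeError, TypeError) as exc:
        raise CohortError(f"malformed result file {path}: {exc}") from exc
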