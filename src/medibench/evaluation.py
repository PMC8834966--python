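"""Scoring of inferred networks against ground truth.

Only the top five most abundant species of each community are evaluated
(20 directed candidate pairs).  Detection quality is measured by
midrank ROC-AUC and by the precision of the top half of the ranked
candidates; group comparisons use medians and Mann--Whitney tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .ground_truth import EffectiveMatrix
from .inference import InferenceResult

__all__ = [
    "DegenerateTruthError",
    "EvaluationTask",
    "BenchmarkRecord",
    "SummaryTable",
    "top_k_species",
    "make_task",
    "roc_auc",
    "precision_at_half",
    "evaluate_result",
    "summarize",
    "records_to_frame",
]


class DegenerateTruthError(ValueError):
    """All-positive or all-negative truth: detection metrics are undefined."""


@dataclass
class EvaluationTask:
    """Flattened directed-pair classification problem.

    ``scores`` are oriented so that larger means "more likely
    interacting" (p-values are negated on construction).
    """

    labels: np.ndarray  # boolean, one per off-diagonal pair (row-major)
    scores: np.ndarray
    classifier: str  # "stat" or "pval"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.labels.shape != self.scores.shape:
            raise ValueError("labels/scores shape mismatch")

    @property
    def n_pairs(self) -> int:
        return self.labels.size

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())


@dataclass
class BenchmarkRecord:
    model_id: str
    tau: int
    sigma: float
    community: int
    method: str
    classifier: str
    auc: float
    precision_half: float
    positives: int


@dataclass
class SummaryTable:
    medians: pd.DataFrame
    median_diff: pd.DataFrame
    mw_pvalues: pd.DataFrame
    significant: pd.DataFrame


def top_k_species(series, k: int = 5) -> np.ndarray:
    """Indices of the ``k`` species with the largest mean abundance in the
    analyzed window; ties broken in favour of the lower index."""
    values = series.values if hasattr(series, "values") else np.asarray(series)
    means = np.asarray(values, dtype=float).mean(axis=0)
    n = means.size
    if k > n:
        raise ValueError(f"k={k} exceeds species count {n}")
    order = np.lexsort((np.arange(n), -means))
    return np.sort(order[:k])


def _offdiag_flat(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat)
    n = mat.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return mat[mask]  # row-major off-diagonal order


def make_task(
    truth_presence: np.ndarray,
    result_matrix: np.ndarray,
    classifier: str,
    use_abs: bool = True,
) -> EvaluationTask:
    """Build a directed-pair task from matched truth and result matrices.

    Statistics are ranked descending (by magnitude when ``use_abs``);
    p-values ascending.
    """
    labels = _offdiag_flat(np.asarray(truth_presence, dtype=bool))
    vals = _offdiag_flat(np.asarray(result_matrix, dtype=float))
    if classifier == "stat":
        scores = np.abs(vals) if use_abs else vals
    elif classifier == "pval":
        scores = -vals
    else:
        raise ValueError("classifier must be 'stat' or 'pval'")
    return EvaluationTask(labels=labels, scores=scores, classifier=classifier)


def roc_auc(task: EvaluationTask) -> float:
    """Midrank (Mann--Whitney) ROC-AUC of the task's ranking."""
    n_pos = task.n_positive
    n_neg = task.n_pairs - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateTruthError(
            f"truth has {n_pos} positives of {task.n_pairs} pairs"
        )
    ranks = stats.rankdata(task.scores)
    r_pos = ranks[task.labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def precision_at_half(task: EvaluationTask) -> float:
    """Precision when the top half of the ranked pairs is selected.

    Ties at the cutoff are resolved deterministically in favour of the
    earlier (row-major) pair.
    """
    n_pos = task.n_positive
    if n_pos == 0 or n_pos == task.n_pairs:
        raise DegenerateTruthError(
            f"truth has {n_pos} positives of {task.n_pairs} pairs"
        )
    n_sel = task.n_pairs // 2
    order = np.lexsort((np.arange(task.n_pairs), -task.scores))
    selected = order[:n_sel]
    return float(task.labels[selected].sum() / n_sel)


def evaluate_result(
    truth: EffectiveMatrix,
    result: InferenceResult,
    series,
    k: int = 5,
    use_abs: bool = True,
) -> List[Tuple[str, float, float, int]]:
    """Evaluate one inference result on the top-``k`` submatrix.

    Returns ``(classifier, auc, precision, n_positive)`` tuples for the
    statistic and the p-value classifiers; degenerate truths yield an
    empty list (with a warning).
    """
    top = top_k_species(series, k=k)
    sub_truth = truth.presence[np.ix_(top, top)]
    out = []
    for classifier, mat in (("stat", result.stat), ("pval", result.pval)):
        sub = mat[np.ix_(top, top)]
        task = make_task(sub_truth, sub, classifier, use_abs=use_abs)
        try:
            auc = roc_auc(task)
            prec = precision_at_half(task)
        except DegenerateTruthError as exc:
            warnings.warn(f"skipping degenerate community: {exc}", stacklevel=2)
            continue
        out.append((classifier, auc, prec, task.n_positive))
    return out


def records_to_frame(records: Iterable[BenchmarkRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def summarize(
    records,
    metric: str = "auc",
    group_cols: Sequence[str] = ("model_id", "method", "classifier"),
    alpha: float = 0.05,
) -> SummaryTable:
    """Group medians, pairwise median differences and Mann--Whitney tests.

    The difference matrix entry (row, col) is median(row) - median(col),
    hence antisymmetric; the significance flag marks two-sided
    Mann--Whitney p-values below ``alpha``.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    groups = {}
    for key, sub in df.groupby(list(group_cols)):
        if not isinstance(key, tuple):
            key = (key,)
        vals = sub[metric].dropna().to_numpy()
        if vals.size:
            groups["|".join(map(str, key))] = vals
    names = sorted(groups)
    medians = pd.DataFrame(
        {"group": names, "median": [float(np.median(groups[g])) for g in names],
         "n": [len(groups[g]) for g in names]}
    ).set_index("group")
    diff = pd.DataFrame(0.0, index=names, columns=names)
    pvals = pd.DataFrame(1.0, index=names, columns=names)
    for a in names:
        for b in names:
            if a == b:
                continue
            diff.loc[a, b] = float(np.median(groups[a]) - np.median(groups[b]))
            try:
                pvals.loc[a, b] = float(
                    stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue
                )
            except ValueError:  # identical constant samples
                pvals.loc[a, b] = 1.0
    return SummaryTable(
        medians=medians, median_diff=diff, mw_pvalues=pvals,
        significant=pvals < alpha,
    )
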